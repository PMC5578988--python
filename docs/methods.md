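# Methods

This note records the models, conventions and numerical choices behind
helixdyn, and what the synthetic-data validation does and does not
demonstrate.

## Data model and residue identity

Structures are ordered atom tables with `(chain, author residue number,
insertion code, atom name)` as the public identity; a dense 0-based index
exists internally but never appears in reports.  This matters because the
literature this kind of analysis serves names residues by author numbering
(K200, D335, S746 …); every output table keeps that convention.  Multi-model
PDB is the mandatory trajectory format (Bio.PDB backend, first-kept altloc
'A'/blank, 3-decimal coordinate precision); XTC/DCD are optional via
MDAnalysis.  The saved-frame spacing `dt` (ps) and the equilibration
`discard_prefix` (frames excluded from every statistic) are part of the
trajectory object, mirroring the common practice of saving positions every
50 ps and discarding the first stretch of production before analysis.

## Chemistry annotation

Donor/acceptor/charged-group roles are assigned purely from residue and atom
names — never coordinates — so annotation is deterministic and reusable
across frames.  Standard amino acids, GDP, water and the mock lipids
(PC/PE head-group chemistry; POPC/POPE spellings are recognized as aliases)
are built in; a YAML table can override or extend per residue.  Salient
choices:

* Histidine is neutral by default (ND1 acceptor, NE2 donor in the common
  tautomer).  A per-residue or global protonation flag makes it a +1 charged
  group and removes the ring nitrogens from the acceptor set — required when
  a doubly protonated His participates in a salt bridge.
* `heavy_only` mode registers donor heavy atoms without hydrogens, for
  crystal structures solved without H; downstream detection then applies the
  distance criterion alone (the LigPlot-style 3.5 Å donor–acceptor census).
* Charged termini are off by default (`include_termini=True` to add them).

## Interaction criteria

* **H-bond:** donor–acceptor heavy distance ≤ 3.5 Å and off-axis angle ≤ 30°.
  The criterion names an angle but not its vertex, and conventions differ
  between tools; here the angle is measured at the *donor* between D→H and
  D→A, with the acceptor-centred alternative selectable (`angle_at`).  Among
  multiple donor hydrogens the smallest angle decides.
* **Salt bridge:** minimum heavy-atom pair distance between opposite-sign
  groups ≤ 6.5 Å (the classifier); the centroid–centroid group distance is
  reported alongside, since group-distance time series are also informative
  when a bridge hovers near the cutoff.
* All cutoffs are inclusive, padded by 1e-9 so that geometry constructed
  exactly at a boundary is not dropped by floating-point roundoff.
* Intra-residue donor–acceptor pairs are excluded by default.
* Candidate pruning uses a KD-tree over acceptors; the test suite and the
  acceptance script hold an independent all-pairs implementation of the same
  criteria and require identical event sets.
* **Persistence** is `100 · present / analyzed` with the denominator counting
  frames after the discard prefix.  Under trajectory concatenation it is the
  frame-weighted mean of the parts (tested).

## Secondary structure

A from-scratch Kabsch–Sander implementation: backbone H-bond energies from
the 0.084·332 electrostatic formula with the −0.5 kcal/mol acceptance and the
best-two-acceptors-per-donor rule; n-turns (3,4,5) give G/H/I via the
two-consecutive-turns minimal-helix rule; parallel/antiparallel bridge
patterns give B and, within ladders, E; turn (T) and bend (S, CA-pseudoangle
> 70°) complete the eight states.  The amide H is read from the structure
when present, otherwise placed 1.0 Å from N anti to the preceding carbonyl.
Two deliberate knobs:

* **π priority.** Modern DSSP dialects let a π-helix pattern outrank α; that
  is the default (`pi_over_h=True`).  The classic ordering is selectable, and
  the oracle-agreement validation uses it because the reference
  implementation (mdtraj's DSSP port) is classic.  The dialects only diverge
  on structures that contain π patterns.
* **Inclusive stability threshold.** A residue whose dominant code holds in
  exactly 90 % of frames counts as stable.  Boundary frames are measure-zero
  in real data; inclusivity makes the planted-truth arithmetic exact and is
  configurable.

Validation measures ≥ 95 % per-residue agreement with mdtraj over a fixture
library (ideal helix, two-strand antiparallel pair, σ = 0.3 Å perturbations);
the measured value is ~98 %.  Heavy-atom fixtures are used for this
comparison so both implementations reconstruct the amide H identically —
with explicit noisy hydrogens the two tools see slightly different energies
near the −0.5 threshold, which is a dialect difference, not an error.

## Geometry

* **Helix axis:** local centres are sliding-window means of consecutive CA
  positions (window 7 ≈ two turns when available, else 4 — a 7-residue mean
  cancels the helical phase almost completely); the axis is the principal
  component of the centres, oriented N→C, with the RMS centre-to-axis
  distance as the fit residual (< 0.1 Å for ideal helices).
* **Crossing angle:** χ = |signed torsion from axis A to axis B about the
  common normal pointing A→B|, in (0°, 180°]; handedness = sign (right ⇔
  negative); orientation from the directed-axes dot product (antiparallel ⇔
  χ > 90°).  Reporting magnitude + handedness rather than one signed scalar
  keeps both community conventions derivable.  A consequence adopted
  throughout: a requested (χ < 90°, antiparallel) dimer is geometrically
  contradictory and the builder rejects it as infeasible.
  χ(A,B) = χ(B,A) exactly; reversing one axis maps χ → 180° − χ.  Parallel
  axes give handedness "indeterminate".
* **Superposition:** standard SVD Kabsch with the determinant correction
  (proper rotations only).  RMSF superposes all frames onto the iteratively
  refined average structure by default (first-frame reference selectable —
  the choice is rarely stated in publications, and average-structure is the
  better-conditioned default).
* **Refined RMSD:** the exclusion rules that have algorithmic definitions
  (RMSF threshold, secondary-structure persistence threshold) are computed;
  criteria with no operational definition (conservation, hypothesized
  conformational-change involvement, template-unresolved segments) enter as
  explicit reason-coded residue lists from the config.  Refined ≤ unrefined
  is *not* asserted in general — it is not mathematically guaranteed — but on
  the planted high-noise-termini fixture the refined mean is lower by
  construction (~55 % in the acceptance run).

## Clustering

GROMOS neighbour-count clustering on the dense pairwise-RMSD matrix
(CA selection by default; a guard errors beyond ~12 000 frames since the
matrix is O(n²)).  Determinism is pinned down where the published rule is
silent: equal neighbour counts break to the lowest frame index, and the
neighbour criterion is inclusive.  Clusters are reported by decreasing size;
the first cluster's centre is the centroid structure.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analyses assume:

* isotropic per-residue Gaussian coordinate noise (so RMSF has the closed
  form σ√3, recovered within 10 % at 200 frames — the superposition absorbs
  a small part, ~(1 − k/3N), well inside that band);
* two-state interaction schedules, either explicit presence vectors
  (persistence is then exact arithmetic: 19-of-50 ⇒ 38.0 %) or Bernoulli
  occupancies (recovery within binomial error, ±3 points at n = 500);
* straight ideal α-helices from canonical (φ = −57°, ψ = −47°) internal
  coordinates, paired into dimers whose axes realize a requested crossing
  angle/orientation/handedness exactly (closure ≤ 2° against the measuring
  code and against the analytic construction);
* a fully extended two-strand antiparallel pair whose inter-strand ladder is
  grid-optimized under the Kabsch–Sander energy;
* coarse pseudo-lipids with real head-group chemistry (PE amine donates, PC
  cannot) and a constructed nucleotide pocket whose heavy-atom 3.5 Å
  donor–acceptor network size is planted (10 contacts, the size of a
  GDP-template network).

Noise is applied *before* schedule enforcement so planted interactions always
pass the detector — test outcomes are deterministic by design.  What the
generator does not emulate: force-field physics, sterics beyond a minimum
distance, correlated motions, solvent, and membrane packing.  Passing tests
therefore demonstrate that the *measurement machinery* is correct and
self-consistent at desk scale, not that any particular biological system
behaves a certain way; the headline percentages of a real 500-ns study are
functions of its trajectories, which a synthetic harness cannot and does not
reproduce.

Problem sizes used throughout the suite and acceptance script — 15–30-residue
helices, 50–500-frame trajectories, ≤ 500-atom random frames, ≤ 30-frame
cluster matrices — were chosen as the smallest scales at which each
statistic's expected value is sharp (binomial error ≤ 3 points, RMSF
sampling error ≪ 10 %).

## Known limitations

* The PDB writer emits fixed-format files with ≤ 4-character atom names and
  ≤ 3-character residue names (hence the PC/PE mock-lipid codes).
* DSSP β-bulge linking and PP-II are not implemented; assignment near ladder
  ends can differ from reference implementations (inside the 95 % band).
* The schematic side chains of generated structures are chemically labelled
  but geometrically coarse; they support detector logic, not packing
  analysis.
* Salt-bridge typing requires user-supplied registers; no coiled-coil
  prediction is performed.
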