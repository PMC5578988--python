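# helixdyn

Structural-dynamics analysis for membrane-protein MD trajectories:
interaction persistence, secondary-structure stability, coiled-coil
electrostatics, transmembrane helix-packing geometry and conformational
clustering — with a synthetic-data generator that plants known ground truth
for validating every stage.

## Who this is for

Researchers characterizing a membrane-inserted protein model (for example a
dynamin-family GTPase such as a mitofusin, with its heptad-repeat bundles and
two-pass transmembrane dimer) from molecular-dynamics output: multi-model PDB
trajectories, optionally XTC/DCD through MDAnalysis.  The library answers the
questions such a study asks frame by frame — *which hydrogen bonds and salt
bridges hold, for what fraction of the simulation, between which author-
numbered residues?* — and reports everything in the field's own vocabulary.

## The statistics at the core

* **Persistence.** For an interaction event *e* and the analyzed frames
  *F* (after discarding an equilibration prefix), the persistence is
  `100 · |{f ∈ F : e holds in f}| / |F|` percent.  H-bonds use a donor–
  acceptor distance ≤ 3.5 Å with an off-axis angle ≤ 30° at the donor
  (distance-only for H-free crystal structures); salt bridges use a minimum
  heavy-atom distance ≤ 6.5 Å between opposite-sign charged groups.  All
  cutoffs are inclusive.
* **Secondary-structure persistence.** Per-frame Kabsch–Sander assignment
  (backbone H-bond energy `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`
  kcal/mol, accepted below −0.5) over the eight states H/G/I/E/B/T/S/−; a
  residue is *stable* when its dominant code persists in ≥ 90 % of frames.
* **Crossing angle χ.** Helix axes are fitted from sliding-window CA centres;
  χ is the magnitude of the signed inter-axis torsion between the directed
  (N→C) axes, in (0°, 180°], with a separate handedness call (right ⇔
  negative torsion) and an orientation call (antiparallel ⇔ χ > 90°).
* **Heptad register typing.** Registers (positions a–g) propagate by modular
  arithmetic from a user-supplied anchor; salt bridges are typed by their
  register pair (e.g. the classic intrahelical i→i+3 "b–e" bridge).
* **GROMOS clustering.** Greedy neighbour-count clustering of the pairwise
  superposed-RMSD matrix at a given cutoff; the centre of the largest cluster
  is the most representative structure (centroid).
* **Refined RMSD.** Per-frame CA RMSD after excluding residues by rule
  (RMSF above threshold, unstable secondary structure, explicit lists for
  template-unresolved/hinge/disordered regions), with a reason-coded mask.

## Worked example

Generate the bundled synthetic demo — a heptad-registered two-helix bundle,
a TM dimer built at χ = 120° (right-handed, antiparallel) carrying GxxxG
motifs, a mock POPC/POPE membrane and a GDP-like nucleotide site, all with
planted interaction schedules — then run the full battery:

```bash
helixdyn demo -o demo --seed 1
helixdyn run -c demo/config.yaml -o out
```

Key lines from the report tables (seed 1):

```
out/pair_persistence.tsv
  D:752-C:721   hbond        19  50   38.0000     # planted 19-of-50 schedule
  A:488-A:485   salt_bridge  50  50  100.0000     # planted b-e bridge
  B:771-A:489   salt_bridge  45  50   90.0000     # planted 0.9-occupancy bridge

out/crossing_angle.tsv (per frame)
  0.0   118.8345  antiparallel  right  9.4191     # target χ = 120°

out/lipid_hbonds.tsv
  PC  51.0   1.0200                               # planted 1 bond/frame
  PE  103.0  2.0600                               # planted 2 bonds/frame

out/ligand_network.tsv
  A:LYS496:NZ~X:GDP901:O1B  3.0727  100.0000 ...  # tight (≤3.5 Å) every frame
```

Every planted truth is recovered: the 19-of-50 hydrogen-bond schedule reads
exactly 38.0 %, the trajectory-averaged crossing angle sits within 2° of the
constructed 120° with the correct orientation and handedness calls, and the
protein–lipid census reproduces the built-in PE > PC preference.  The same
tables for real data are produced by pointing `config.yaml` at your own
topology/trajectory and selections.

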