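"""Per-frame interaction detection and the frame-persistence statistic.

Criteria (all cutoffs inclusive):

* hydrogen bond — donor–acceptor heavy-atom distance ≤ 3.5 Å and, with
  explicit hydrogens, an off-axis angle ≤ 30° measured at the donor between
  the D→H and D→A vectors (the acceptor-centred alternative is available via
  ``angle_at='acceptor'``, the D→H vs A→H angle); heavy-only annotations use
  the distance criterion alone.
* salt bridge — opposite-sign charged groups whose minimum heavy-atom pair
  distance is ≤ 6.5 Å; the centroid–centroid group distance is also reported.
* persistence — the percentage of analyzed frames (after the equilibration
  discard) in which the event's criterion holds.

Candidate pairs are pruned with a KD-tree; an all-pairs reference
implementation of the same criteria lives in the test suite as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Frame, ResidueKey, Trajectory
from .structure_io import ChemistryAnnotation

__all__ = [
    "HBondEvent",
    "SaltBridgeEvent",
    "PersistenceRecord",
    "LigandContactSeries",
    "detect_hbonds",
    "detect_salt_bridges",
    "persistence",
    "hbond_pair_detector",
    "salt_bridge_pair_detector",
    "ligand_contact_network",
    "lipid_hbond_counts",
]

HBOND_DIST = 3.5      # Å
HBOND_ANGLE = 30.0    # degrees
SALT_BRIDGE_DIST = 6.5  # Å
_EPS = 1e-9           # padding so inclusive boundaries survive roundoff


@dataclass(frozen=True)
class HBondEvent:
    donor: int                   # dense atom index
    acceptor: int
    hydrogen: int | None
    distance: float              # donor-acceptor, Å
    angle: float | None          # degrees; None in heavy-only mode

    def key(self, frame: Frame) -> tuple[str, str]:
        return (frame.atoms[self.donor].label(), frame.atoms[self.acceptor].label())


@dataclass(frozen=True)
class SaltBridgeEvent:
    negative: ResidueKey
    positive: ResidueKey
    min_distance: float          # minimum heavy-atom pair distance, Å
    group_distance: float        # centroid-centroid distance, Å

    def pair_label(self, frame: Frame | None = None) -> str:
        return f"{self.negative}-{self.positive}"


def detect_hbonds(
    frame: Frame,
    sel_a: np.ndarray | None,
    sel_b: np.ndarray | None,
    annotation: ChemistryAnnotation,
    dist_cutoff: float = HBOND_DIST,
    angle_cutoff: float = HBOND_ANGLE,
    angle_at: str = "donor",
    exclude_same_residue: bool = True,
) -> list[HBondEvent]:
    """All H-bonds with donor in one selection and acceptor in the other.

    Both directions (donor∈A→acceptor∈B and donor∈B→acceptor∈A) are
    returned, so the result is symmetric in the two selections.  ``None``
    selections mean "all atoms".  Raises if the annotation carries explicit
    hydrogens for no donor while ``explicit_h`` mode is requested on an
    H-free structure.
    """
    if annotation.mode == "explicit_h" and not any(
        d.hydrogens for d in annotation.donors
    ) and annotation.is_protein.any():
        raise ValueError(
            "explicit_h annotation found no donor hydrogens on a protein "
            "frame; re-annotate with mode='heavy_only'"
        )
    n = frame.n_atoms
    in_a = np.zeros(n, bool)
    in_b = np.zeros(n, bool)
    in_a[np.arange(n) if sel_a is None else np.asarray(sel_a, int)] = True
    in_b[np.arange(n) if sel_b is None else np.asarray(sel_b, int)] = True

    acceptors = np.asarray(annotation.acceptors, int)
    if acceptors.size == 0 or not annotation.donors:
        return []
    tree = cKDTree(frame.coords[acceptors])
    events: list[HBondEvent] = []
    for donor in annotation.donors:
        di = donor.atom
        if not (in_a[di] or in_b[di]):
            continue
        near = tree.query_ball_point(frame.coords[di], dist_cutoff + 2 * _EPS)
        for k in near:
            ai = int(acceptors[k])
            if ai == di:
                continue
            if not ((in_a[di] and in_b[ai]) or (in_b[di] and in_a[ai])):
                continue
            if exclude_same_residue and (
                frame.atoms[di].residue_key == frame.atoms[ai].residue_key
            ):
                continue
            dist = float(np.linalg.norm(frame.coords[ai] - frame.coords[di]))
            if dist > dist_cutoff + _EPS:
                continue
            if annotation.mode == "heavy_only" or not donor.hydrogens:
                if annotation.mode == "explicit_h":
                    continue  # donor without H cannot donate in explicit mode
                events.append(HBondEvent(di, ai, None, dist, None))
                continue
            best: tuple[float, int] | None = None
            for hi in donor.hydrogens:
                ang = _off_axis_angle(frame.coords, di, hi, ai, angle_at)
                if best is None or ang < best[0]:
                    best = (ang, hi)
            assert best is not None
            if best[0] <= angle_cutoff + _EPS:
                events.append(HBondEvent(di, ai, best[1], dist, best[0]))
    return events


def _off_axis_angle(coords: np.ndarray, di: int, hi: int, ai: int,
                    angle_at: str) -> float:
    if angle_at == "donor":
        u = coords[hi] - coords[di]
        v = coords[ai] - coords[di]
    elif angle_at == "acceptor":
        u = coords[hi] - coords[di]
        v = coords[hi] - coords[ai]
    else:
        raise ValueError(f"unknown angle_at {angle_at!r}")
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_salt_bridges(
    frame: Frame,
    annotation: ChemistryAnnotation,
    cutoff: float = SALT_BRIDGE_DIST,
) -> list[SaltBridgeEvent]:
    """Opposite-sign charged-group pairs within the (inclusive) cutoff."""
    neg = [g for g in annotation.charged_groups if g.sign < 0]
    pos = [g for g in annotation.charged_groups if g.sign > 0]
    events: list[SaltBridgeEvent] = []
    for gn in neg:
        cn = frame.coords[list(gn.atoms)]
        for gp in pos:
            cp = frame.coords[list(gp.atoms)]
            d = np.linalg.norm(cn[:, None, :] - cp[None, :, :], axis=2)
            dmin = float(d.min())
            if dmin <= cutoff + 1e-9:
                events.append(SaltBridgeEvent(
                    negative=gn.residue, positive=gp.residue,
                    min_distance=dmin,
                    group_distance=float(np.linalg.norm(
                        cn.mean(axis=0) - cp.mean(axis=0))),
                ))
    return events


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

@dataclass
class PersistenceRecord:
    """Fraction of analyzed frames in which one interaction event holds."""

    key: str
    frames_present: int
    frames_analyzed: int
    present: np.ndarray          # per analyzed frame

    @property
    def percent(self) -> float:
        return 100.0 * self.frames_present / self.frames_analyzed


def persistence(
    traj: Trajectory,
    key: str,
    detector: Callable[[Frame], bool],
) -> PersistenceRecord:
    """Evaluate a per-frame detector over the analyzed frames of a trajectory.

    The persistence is ``100 * frames_present / frames_analyzed`` with the
    denominator counting frames after the discard prefix.
    """
    if traj.n_analyzed < 1:
        raise ValueError("no analyzed frames")
    present = np.zeros(traj.n_analyzed, bool)
    for row, (_, frame) in enumerate(traj.analyzed_frames()):
        present[row] = bool(detector(frame))
    return PersistenceRecord(key=key, frames_present=int(present.sum()),
                             frames_analyzed=traj.n_analyzed, present=present)


def hbond_pair_detector(
    traj: Trajectory,
    donor_residue: ResidueKey,
    acceptor_residue: ResidueKey,
    annotation: ChemistryAnnotation,
    dist_cutoff: float = HBOND_DIST,
    angle_cutoff: float = HBOND_ANGLE,
) -> Callable[[Frame], bool]:
    """Detector: any H-bond between two residues (either donation direction)."""
    keys = {a.residue_key for a in traj.atoms}
    for rk in (donor_residue, acceptor_residue):
        if rk not in keys:
            raise ValueError(f"residue {rk} not present in topology "
                             f"(pair {donor_residue}-{acceptor_residue})")
    sel_a = np.asarray([i for i, a in enumerate(traj.atoms)
                        if a.residue_key == donor_residue], int)
    sel_b = np.asarray([i for i, a in enumerate(traj.atoms)
                        if a.residue_key == acceptor_residue], int)

    def detector(frame: Frame) -> bool:
        return bool(detect_hbonds(frame, sel_a, sel_b, annotation,
                                  dist_cutoff, angle_cutoff))
    return detector


def salt_bridge_pair_detector(
    traj: Trajectory,
    res_a: ResidueKey,
    res_b: ResidueKey,
    annotation: ChemistryAnnotation,
    cutoff: float = SALT_BRIDGE_DIST,
) -> Callable[[Frame], bool]:
    keys = {a.residue_key for a in traj.atoms}
    for rk in (res_a, res_b):
        if rk not in keys:
            raise ValueError(f"residue {rk} not present in topology")
    pair = {res_a, res_b}

    def detector(frame: Frame) -> bool:
        for ev in detect_salt_bridges(frame, annotation, cutoff):
            if {ev.negative, ev.positive} == pair:
                return True
        return False
    return detector


# --------------------------------------------------------------------------
# ligand contact network
# --------------------------------------------------------------------------

@dataclass
class LigandContactSeries:
    """Per-frame donor–acceptor distance for one named pair, with the
    tight (≤3.5 Å) / loose (≤4.0 Å) / none distance classes."""

    label: str
    donor: int
    acceptor: int
    distances: np.ndarray        # Å per analyzed frame
    tight_cutoff: float = 3.5
    loose_cutoff: float = 4.0

    @property
    def classes(self) -> np.ndarray:
        out = np.full(self.distances.shape, "none", dtype="U5")
        out[self.distances <= self.loose_cutoff] = "loose"
        out[self.distances <= self.tight_cutoff] = "tight"
        return out

    @property
    def tight_persistence(self) -> float:
        return 100.0 * float(np.mean(self.distances <= self.tight_cutoff))


def ligand_contact_network(
    traj: Trajectory,
    pairs: Sequence[tuple[tuple[str, int, str], tuple[str, int, str]]],
    tight_cutoff: float = 3.5,
    loose_cutoff: float = 4.0,
) -> list[LigandContactSeries]:
    """Distance time series for named donor-atom ↔ acceptor-atom pairs.

    Each pair is ((chain, resid, atom), (chain, resid, atom)); unresolvable
    pairs raise before any computation.
    """
    frame0 = traj.frame(0)
    resolved = []
    for dspec, aspec in pairs:
        di = frame0.atom_index(*dspec[:2], dspec[2])
        ai = frame0.atom_index(*aspec[:2], aspec[2])
        label = f"{frame0.atoms[di].label()}~{frame0.atoms[ai].label()}"
        resolved.append((label, di, ai))
    idx = traj.analyzed_indices
    out = []
    for label, di, ai in resolved:
        d = np.linalg.norm(traj.coords[idx, di] - traj.coords[idx, ai], axis=1)
        out.append(LigandContactSeries(label=label, donor=di, acceptor=ai,
                                       distances=d, tight_cutoff=tight_cutoff,
                                       loose_cutoff=loose_cutoff))
    return out


# --------------------------------------------------------------------------
# protein-lipid H-bond census
# --------------------------------------------------------------------------

def lipid_hbond_counts(
    traj: Trajectory,
    annotation: ChemistryAnnotation,
    dist_cutoff: float = HBOND_DIST,
    angle_cutoff: float = HBOND_ANGLE,
) -> dict[str, dict[str, float]]:
    """Protein–lipid H-bond counts per lipid species.

    Returns ``{species: {'total': …, 'mean_per_frame': …}}`` over the
    analyzed frames; species present in the topology but never bonded report
    zero.
    """
    prot = np.nonzero(annotation.is_protein)[0]
    lip = np.nonzero(annotation.is_lipid)[0]
    species = sorted({traj.atoms[i].resname for i in lip})
    totals = {s: 0 for s in species}
    n_frames = 0
    if prot.size and lip.size:
        for _, frame in traj.analyzed_frames():
            n_frames += 1
            for ev in detect_hbonds(frame, prot, lip, annotation,
                                    dist_cutoff, angle_cutoff):
                datom = frame.atoms[ev.donor]
                aatom = frame.atoms[ev.acceptor]
                lipid_atom = datom if annotation.is_lipid[ev.donor] else aatom
                totals[lipid_atom.resname] += 1
    else:
        n_frames = traj.n_analyzed
    return {
        s: {"total": float(totals[s]),
            "mean_per_frame": totals[s] / n_frames if n_frames else 0.0}
        for s in species
    }
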