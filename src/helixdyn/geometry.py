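"""Helix-axis and packing geometry, superposition, RMSD/RMSF series.

Crossing-angle convention
-------------------------
Both helix axes are *directed* N→C.  The crossing angle χ is the magnitude of
the signed inter-axis torsion, reported in (0°, 180°]: the signed angle is
measured from axis A to axis B about the common normal pointing from A to B,
so χ > 90° means the directed axes are antiparallel.  Handedness is the sign
of that torsion — negative ⇔ right-handed packing, the convention under which
(small)xxx(small)-mediated TM dimers are right-handed.  Reporting magnitude +
handedness (rather than one signed scalar) keeps both of the field's habits
recoverable from the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import Frame, ResidueKey, Trajectory

__all__ = [
    "HelixAxis",
    "CrossingAngleResult",
    "GeometrySeries",
    "RMSFProfile",
    "ExclusionRules",
    "kabsch_superpose",
    "fit_helix_axis",
    "crossing_angle",
    "rmsd_series",
    "rmsf",
    "refined_rmsd",
]


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with the optimal proper rotation (det = +1) and
    translation such that ``mobile @ R.T + t`` best matches ``reference``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, t, rmsd


def _rmsd_after_fit(mobile: np.ndarray, reference: np.ndarray) -> float:
    return kabsch_superpose(mobile, reference)[2]


# --------------------------------------------------------------------------
# helix axes and crossing angle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixAxis:
    point: np.ndarray          # a point on the axis (centroid of local centers)
    direction: np.ndarray      # unit vector, oriented N -> C
    n_residues: int
    residual: float            # RMS distance of local helix centers from the axis


def fit_helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Fit a straight axis to an α-helix from its ordered CA positions.

    Local helix centers are sliding-window means of consecutive CAs (window 7
    ≈ two turns when available, else 4); the axis is the principal component
    of those centers, oriented N→C.
    """
    ca = np.asarray(ca_coords, float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("expected (n, 3) CA coordinates")
    m = ca.shape[0]
    if m < 5:
        raise ValueError(f"need at least 5 CA atoms to fit a helix axis, got {m}")
    w = 7 if m >= 8 else 4
    centers = np.stack([ca[i:i + w].mean(axis=0) for i in range(m - w + 1)])
    centroid = centers.mean(axis=0)
    dev = centers - centroid
    if np.allclose(dev, 0.0, atol=1e-10):
        direction = ca[-1] - ca[0]
    else:
        _, _, Vt = np.linalg.svd(dev, full_matrices=False)
        direction = Vt[0]
    nc = ca[-1] - ca[0]
    if np.dot(direction, nc) < 0:
        direction = -direction
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("degenerate CA set: cannot orient axis")
    direction = direction / norm
    perp = dev - np.outer(dev @ direction, direction)
    residual = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    return HelixAxis(point=centroid, direction=direction, n_residues=m,
                     residual=residual)


@dataclass(frozen=True)
class CrossingAngleResult:
    chi: float                    # degrees, in (0, 180]
    signed_chi: float             # degrees, in (-180, 180]; sign = handedness
    orientation: str              # 'parallel' | 'antiparallel'
    handedness: str               # 'left' | 'right' | 'indeterminate'
    closest_approach: float       # Å between the two axis lines


_PARALLEL_TOL = 1e-8


def crossing_angle(axis_a: HelixAxis, axis_b: HelixAxis) -> CrossingAngleResult:
    """Signed crossing angle between two directed helix axes (see module docs)."""
    ua, ub = axis_a.direction, axis_b.direction
    pa, pb = axis_a.point, axis_b.point
    n = np.cross(ua, ub)
    dot = float(np.clip(np.dot(ua, ub), -1.0, 1.0))
    w0 = pb - pa
    if np.linalg.norm(n) < _PARALLEL_TOL:
        # parallel axes: distance between the lines, handedness undefined
        perp = w0 - np.dot(w0, ua) * ua
        chi = 0.0 if dot > 0 else 180.0
        orientation = "parallel" if dot > 0 else "antiparallel"
        return CrossingAngleResult(chi=chi, signed_chi=chi, orientation=orientation,
                                   handedness="indeterminate",
                                   closest_approach=float(np.linalg.norm(perp)))
    nhat = n / np.linalg.norm(n)
    offset = float(np.dot(w0, nhat))
    # common normal pointing from axis A toward axis B
    what = nhat if offset >= 0 else -nhat
    signed = float(np.degrees(np.arctan2(np.dot(n, what), dot)))
    chi = abs(signed)
    if chi == 0.0:
        chi = 180.0 if dot < 0 else 0.0
    orientation = "parallel" if dot >= 0 else "antiparallel"
    handedness = "right" if signed < 0 else "left"
    return CrossingAngleResult(chi=chi, signed_chi=signed, orientation=orientation,
                               handedness=handedness,
                               closest_approach=abs(offset))


# --------------------------------------------------------------------------
# RMSD / RMSF series
# --------------------------------------------------------------------------

@dataclass
class GeometrySeries:
    times: np.ndarray                          # ps, analyzed frames only
    rmsd: dict[str, np.ndarray]                # Å per named selection
    mask: dict[ResidueKey, tuple[str, ...]] | None = None


@dataclass
class RMSFProfile:
    residues: list[ResidueKey]
    values: np.ndarray                         # Å, same order as residues

    def as_dict(self) -> dict[ResidueKey, float]:
        return {k: float(v) for k, v in zip(self.residues, self.values)}


def _default_fit_indices(traj: Trajectory) -> np.ndarray:
    ca = np.asarray([i for i, a in enumerate(traj.atoms) if a.name == "CA"], int)
    return ca if ca.size >= 3 else np.arange(traj.n_atoms)


def rmsd_series(
    traj: Trajectory,
    reference: Frame | int = 0,
    selections: Mapping[str, np.ndarray] | None = None,
    fit: np.ndarray | None = None,
) -> GeometrySeries:
    """Per-frame RMSD against a reference after superposing on a fit selection.

    ``selections`` maps names to dense atom indices measured after the fit;
    the fit selection (default: all CA) and measure selections may differ.
    """
    ref = traj.frame(reference) if isinstance(reference, (int, np.integer)) else reference
    if fit is None:
        fit = _default_fit_indices(traj)
    fit = np.asarray(fit, int)
    if fit.size == 0:
        raise ValueError("empty fit selection")
    if selections is None:
        selections = {"all": np.arange(traj.n_atoms)}
    sels = {name: np.asarray(ix, int) for name, ix in selections.items()}
    for name, ix in sels.items():
        if ix.size == 0:
            raise ValueError(f"empty selection {name!r}")
        if ix.max() >= traj.n_atoms:
            raise ValueError(f"selection {name!r} out of range")
    out = {name: np.empty(traj.n_analyzed) for name in sels}
    for row, (fi, frame) in enumerate(traj.analyzed_frames()):
        R, t, _ = kabsch_superpose(frame.coords[fit], ref.coords[fit])
        moved = frame.coords @ R.T + t
        for name, ix in sels.items():
            d = moved[ix] - ref.coords[ix]
            out[name][row] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return GeometrySeries(times=traj.times[traj.analyzed_indices], rmsd=out)


def _superposed_stack(traj: Trajectory, fit: np.ndarray,
                      reference: str = "average") -> np.ndarray:
    """Frames superposed on the fit selection; reference = 'average' or 'first'."""
    idx = traj.analyzed_indices
    coords = traj.coords[idx]
    ref = coords[0]
    for _ in range(2 if reference == "average" else 1):
        moved = np.empty_like(coords)
        for k in range(coords.shape[0]):
            R, t, _ = kabsch_superpose(coords[k][fit], ref[fit])
            moved[k] = coords[k] @ R.T + t
        coords = moved
        if reference == "first":
            break
        ref = coords.mean(axis=0)
    return coords


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    reference: str = "average",
) -> RMSFProfile:
    """Per-residue RMSF about the time-average structure after superposition.

    ``reference='average'`` (default) superposes onto the iteratively refined
    mean structure; ``'first'`` onto the first analyzed frame.
    """
    if traj.n_analyzed < 2:
        raise ValueError("RMSF needs at least 2 analyzed frames")
    if selection is None:
        selection = _default_fit_indices(traj)
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise ValueError("empty selection")
    coords = _superposed_stack(traj, selection, reference=reference)
    mean = coords.mean(axis=0)
    msf = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)  # per atom
    sel_set = set(int(i) for i in selection)
    residues: list[ResidueKey] = []
    values: list[float] = []
    frame0 = traj.frame(0)
    for key, _resname, idxs in frame0.residues():
        used = [i for i in idxs if i in sel_set]
        if not used:
            continue
        residues.append(key)
        values.append(float(np.sqrt(np.mean(msf[used]))))
    return RMSFProfile(residues=residues, values=np.asarray(values))


# --------------------------------------------------------------------------
# refined RMSD with exclusion mask
# --------------------------------------------------------------------------

@dataclass
class ExclusionRules:
    """Residue-exclusion rules for the refined RMSD.

    ``rmsf_threshold``: exclude residues with RMSF above this (Å).
    ``explicit``: reason-code -> residues to exclude outright (covers clauses
    with no algorithmic definition: template-unresolved, disorder-predicted,
    hinge, progressive loss of folding — supplied by config).
    ``secstruct_min_persistence``: exclude residues whose dominant secondary
    structure persists in fewer than this fraction of frames (requires
    ``secstruct_persistence``: residue -> fraction).
    """

    rmsf_threshold: float | None = None
    explicit: Mapping[str, Sequence[ResidueKey]] = field(default_factory=dict)
    secstruct_min_persistence: float | None = None
    secstruct_persistence: Mapping[ResidueKey, float] | None = None


def refined_rmsd(
    traj: Trajectory,
    rules: ExclusionRules,
    reference: Frame | int = 0,
    rmsf_profile: RMSFProfile | None = None,
) -> GeometrySeries:
    """Refined RMSD: per-frame CA RMSD over residues passing the exclusion rules.

    The returned series carries the exclusion mask (residue -> reason codes).
    With no rules this equals ``rmsd_series`` over all CA atoms.
    """
    mask: dict[ResidueKey, list[str]] = {}

    def _flag(key: ResidueKey, reason: str) -> None:
        mask.setdefault(key, []).append(reason)

    if rules.rmsf_threshold is not None:
        prof = rmsf_profile if rmsf_profile is not None else rmsf(traj)
        for key, val in zip(prof.residues, prof.values):
            if val > rules.rmsf_threshold:
                _flag(key, "high_rmsf")
    for reason, keys in rules.explicit.items():
        for key in keys:
            _flag(key, reason)
    if rules.secstruct_min_persistence is not None:
        if rules.secstruct_persistence is None:
            raise ValueError("secstruct_min_persistence set but no persistence map given")
        for key, frac in rules.secstruct_persistence.items():
            if frac < rules.secstruct_min_persistence:
                _flag(key, "unstable_secstruct")

    excluded = set(mask)
    keep = np.asarray(
        [i for i, a in enumerate(traj.atoms)
         if a.name == "CA" and a.residue_key not in excluded],
        int,
    )
    if keep.size == 0:
        raise ValueError("exclusion rules removed every residue")
    series = rmsd_series(traj, reference=reference,
                         selections={"refined": keep}, fit=keep)
    series.mask = {k: tuple(v) for k, v in mask.items()}
    return series
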