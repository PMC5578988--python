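"""Synthetic structures and trajectories with planted ground truth.

Every generator is deterministic given its seed.  The trajectories emulate the
statistical structure that the analysis stack assumes about production MD
output — per-atom Gaussian positional noise around a reference conformation
and two-state (on/off) interaction schedules with known occupancy — so that
persistence, RMSF, secondary-structure stability and cluster structure are
known by construction.  There is no force field and no sterics beyond a
minimum-distance check: physical realism is an explicit non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import AtomRecord, Frame, ResidueKey, Trajectory
from .geometry import fit_helix_axis
from .structure_io import annotate_chemistry

__all__ = [
    "CrickParameters",
    "InteractionSchedule",
    "NoiseModel",
    "AtomSpec",
    "build_ideal_helix",
    "build_antiparallel_sheet",
    "build_coiled_dimer",
    "generate_trajectory",
    "build_membrane_mock",
    "build_nucleotide_pocket",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


# --------------------------------------------------------------------------
# internal-coordinate (NeRF) construction
# --------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C with |CD|=bond, angle(B,C,D) and torsion(A,B,C,D)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# minimal side-chain topologies: linear stem from CB, plus terminal forks.
# geometry is schematic beyond CB — only atom identities and rough reach matter
# to the hydrogen-bond / charge chemistry downstream.
_STEMS: dict[str, list[str]] = {
    "ALA": [], "GLY": [],
    "SER": ["OG"], "CYS": ["SG"], "THR": [],
    "VAL": [], "LEU": ["CG"], "ILE": ["CG1", "CD1"],
    "MET": ["CG", "SD", "CE"], "PHE": ["CG", "CZ"],
    "PRO": ["CG", "CD"], "TRP": ["CG", "NE1"],
    "TYR": ["CG", "CZ", "OH"],
    "LYS": ["CG", "CD", "CE", "NZ"],
    "ARG": ["CG", "CD", "NE", "CZ"],
    "ASP": ["CG"], "GLU": ["CG", "CD"],
    "ASN": ["CG"], "GLN": ["CG", "CD"],
    "HIS": ["CG"],
}
# forks off the last stem atom (or CB when the stem is empty)
_FORKS: dict[str, tuple[str, str]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1", "ND2"), "GLN": ("OE1", "NE2"),
    "ARG": ("NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "THR": ("OG1", "CG2"), "VAL": ("CG1", "CG2"), "LEU": ("CD1", "CD2"),
}
# polar hydrogens attached to terminal donor heavy atoms
_POLAR_HS: dict[str, dict[str, tuple[str, ...]]] = {
    "SER": {"OG": ("HG",)}, "THR": {"OG1": ("HG1",)}, "TYR": {"OH": ("HH",)},
    "CYS": {"SG": ("HG",)},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "ASN": {"ND2": ("HD21", "HD22")}, "GLN": {"NE2": ("HE21", "HE22")},
    "HIS": {"NE2": ("HE2",)}, "TRP": {"NE1": ("HE1",)},
}


@dataclass(frozen=True)
class HelixGeometry:
    phi: float = -57.0      # degrees; canonical α-helix
    psi: float = -47.0
    omega: float = 180.0


def build_ideal_helix(
    sequence: str,
    geometry: HelixGeometry = HelixGeometry(),
    chain: str = "A",
    first_resid: int = 1,
    with_hydrogens: bool = True,
) -> Frame:
    """Build a peptide with uniform (φ, ψ) — an ideal α-helix by default.

    Backbone N, CA, C, O placed from canonical covalent geometry; CB for
    non-Gly; schematic polar side-chain atoms and (optionally) polar
    hydrogens, with the backbone amide H in the peptide plane anti to the
    preceding carbonyl (the Kabsch–Sander convention).
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 4:
        raise ValueError(f"sequence must have >= 4 residues, got {len(sequence)}")
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")

    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = [0]

    def add(name: str, resname: str, resid: int, pos: np.ndarray) -> None:
        serial[0] += 1
        element = name[0] if name[0].isalpha() else name[1]
        records.append(AtomRecord(serial[0], name, element.capitalize(),
                                  resname, resid, chain))
        coords.append(np.asarray(pos, float))

    prev = None  # (N, CA, C, O) of previous residue
    for i, letter in enumerate(sequence):
        resname = ONE_TO_THREE[letter]
        resid = first_resid + i
        if prev is None:
            n = np.zeros(3)
            ca = np.array([1.458, 0.0, 0.0])
            # angle(N, CA, C) = 111.2 deg in the xy plane
            c = ca + 1.525 * np.array([math.cos(math.radians(180.0 - 111.2)),
                                       math.sin(math.radians(180.0 - 111.2)), 0.0])
        else:
            pn, pca, pc, po = prev
            n = _place_atom(pn, pca, pc, 1.329, 116.2, geometry.psi)
            ca = _place_atom(pca, pc, n, 1.458, 121.7, geometry.omega)
            c = _place_atom(pc, n, ca, 1.525, 111.2, geometry.phi)
        o = _place_atom(n, ca, c, 1.231, 120.8, geometry.psi + 180.0)

        add("N", resname, resid, n)
        if with_hydrogens and prev is not None and resname != "PRO":
            pn, pca, pc, po = prev
            h = n + 1.01 * _unit(pc - po)
            add("H", resname, resid, h)
        add("CA", resname, resid, ca)
        add("C", resname, resid, c)
        add("O", resname, resid, o)

        if resname != "GLY":
            cb = _place_atom(n, c, ca, 1.53, 110.5, -122.6)
            add("CB", resname, resid, cb)
            u = _unit(cb - ca)
            p_raw = (ca - n) - np.dot(ca - n, u) * u
            p = _unit(p_raw) if np.linalg.norm(p_raw) > 1e-8 else _unit(np.cross(u, [0, 0, 1.0]))
            positions: dict[str, np.ndarray] = {"CB": cb}
            tip = cb
            for k, name in enumerate(_STEMS[resname]):
                tip = cb + 1.35 * (k + 1) * u + 0.45 * ((-1) ** k) * p
                positions[name] = tip
                add(name, resname, resid, tip)
            if resname in _FORKS:
                na, nb = _FORKS[resname]
                fa = tip + 1.28 * _unit(u + 0.6 * p)
                fb = tip + 1.28 * _unit(u - 0.6 * p)
                positions[na], positions[nb] = fa, fb
                add(na, resname, resid, fa)
                add(nb, resname, resid, fb)
            if with_hydrogens:
                for heavy, hnames in _POLAR_HS.get(resname, {}).items():
                    if heavy not in positions:
                        continue
                    hv = positions[heavy]
                    out = _unit(hv - ca)
                    for j, hname in enumerate(hnames):
                        tilt = 0.25 * ((-1) ** j) * p + 0.12 * j * u
                        add(hname, resname, resid, hv + 1.0 * _unit(out + tilt))
        prev = (n, ca, c, o)

    return Frame(records, np.asarray(coords))


_SHEET_EBOND = -0.5


def build_antiparallel_sheet(
    sequence: str = "AGAGAGA",
    chain_a: str = "A",
    chain_b: str = "B",
    first_resid: int = 1,
) -> Frame:
    """Two-strand antiparallel β pair with an inter-strand H-bond ladder.

    Strand A is built fully extended (φ=ψ=180°, planar, so the rigid 2-fold
    pairing can be near-ideal); strand B is its 2-fold rotation about an
    in-sheet axis, translated by a grid-searched offset that maximizes the
    strength of the inter-strand backbone H-bond ladder under the
    Kabsch–Sander energy criterion.
    """
    from .secondary_structure import backbone_hbond_energies

    strand = build_ideal_helix(sequence, HelixGeometry(phi=-180.0, psi=180.0),
                               chain=chain_a, first_resid=first_resid,
                               with_hydrogens=True)
    # canonicalize: CA centroid at origin, strand axis along +x
    ca_idx = strand.select(names=["CA"])
    ca = strand.coords[ca_idx]
    Ralign = _rotation_aligning(ca[-1] - ca[0], np.array([1.0, 0.0, 0.0]))
    coords_a = (strand.coords - ca.mean(axis=0)) @ Ralign.T
    strand = Frame(strand.atoms, coords_a)
    # 2-fold rotation about the y axis: +x strand becomes an antiparallel -x strand
    R = np.diag([-1.0, 1.0, -1.0])

    def candidate(shift: np.ndarray) -> Frame:
        b_coords = strand.coords @ R.T + shift
        records = [
            AtomRecord(a.serial + strand.n_atoms, a.name, a.element,
                       a.resname, a.resid + 100, chain_b)
            for a in strand.atoms
        ]
        return Frame(tuple(strand.atoms) + tuple(records),
                     np.concatenate([strand.coords, b_coords]))

    chain_mask = None

    def score(shift: np.ndarray) -> tuple[int, float]:
        nonlocal chain_mask
        frame = candidate(shift)
        if _min_interchain_dist(frame) < 2.4:
            return (-1, np.inf)
        keys, E = backbone_hbond_energies(frame)
        if chain_mask is None:
            ka = np.array([k.chain for k in keys])
            chain_mask = ka[:, None] != ka[None, :]
        inter = E.copy()
        inter[~chain_mask] = np.inf
        nbonds = int(np.sum(inter < _SHEET_EBOND))
        total = float(np.sum(inter[inter < _SHEET_EBOND]))
        return (nbonds, total)

    xhat = np.array([1.0, 0.0, 0.0])
    best_shift, best_key = None, (-1, np.inf)
    for beta in np.arange(0.0, 360.0, 15.0):
        direction = np.array([0.0, math.cos(math.radians(beta)),
                              math.sin(math.radians(beta))])
        for mag in np.arange(4.0, 5.81, 0.2):
            for da in np.arange(-3.5, 3.51, 0.25):
                shift = da * xhat + mag * direction
                strong, total = score(shift)
                if strong < 0:
                    continue
                key = (strong, total)
                if key[0] > best_key[0] or (key[0] == best_key[0] and key[1] < best_key[1]):
                    best_key, best_shift = key, shift
    if best_shift is None or best_key[0] < 4:
        raise RuntimeError(
            "could not realize an inter-strand H-bond ladder; bulky schematic "
            "side chains can forbid close pairing — use small residues (G/A)"
        )
    # local refinement around the coarse optimum
    for step in (0.1, 0.04):
        improved = True
        while improved:
            improved = False
            for axis in range(3):
                for sign in (-1.0, 1.0):
                    trial = best_shift.copy()
                    trial[axis] += sign * step
                    strong, total = score(trial)
                    key = (strong, total)
                    if key[0] > best_key[0] or (key[0] == best_key[0] and key[1] < best_key[1]):
                        best_key, best_shift = key, trial
                        improved = True
    return candidate(best_shift)


def _min_interchain_dist(frame: Frame) -> float:
    chains = np.array([a.chain for a in frame.atoms])
    heavy = np.array([a.element != "H" for a in frame.atoms])
    first = frame.coords[(chains == chains[0]) & heavy]
    second = frame.coords[(chains != chains[0]) & heavy]
    d = np.linalg.norm(first[:, None, :] - second[None, :, :], axis=2)
    return float(d.min())


# --------------------------------------------------------------------------
# Crick-style two-helix dimers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CrickParameters:
    """Target geometry of a two-helix dimer.

    ``radius`` is the superhelical radius (half the axis-axis separation);
    ``chi`` the target crossing angle between the *directed* N→C axes, so
    χ > 90° implies an antiparallel pair.  ``orientation`` must be consistent
    with χ (parallel ⇔ χ < 90°); contradictory combinations are infeasible
    and rejected.  Handedness is realized as the sign of the inter-axis
    torsion (right ⇔ negative).
    """

    radius: float = 4.7
    residues_per_turn: float = 3.6
    rise_per_residue: float = 1.5
    pitch: float | None = None
    chi: float = 120.0
    orientation: str = "antiparallel"
    handedness: str = "right"


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180° about any axis perpendicular to a
        axis = _unit(np.cross(a, [1.0, 0.0, 0.0]) if abs(a[0]) < 0.9
                     else np.cross(a, [0.0, 1.0, 0.0]))
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * K @ K
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / (np.linalg.norm(v) ** 2))


def build_coiled_dimer(seq_a: str, seq_b: str, crick: CrickParameters = CrickParameters()) -> Frame:
    """Two α-helices (chains A, B) realizing the requested crossing geometry.

    The helices are straight ideal α-helices whose axes are skew lines
    separated by ``2*radius`` along their common normal, tilted to produce the
    requested χ, orientation and handedness.
    """
    if len(seq_a) < 10 or len(seq_b) < 10:
        raise ValueError("both sequences must have >= 10 residues")
    chi = float(crick.chi)
    if not (0.0 < chi <= 180.0):
        raise ValueError(f"chi must be in (0, 180], got {chi}")
    if crick.radius <= 0:
        raise ValueError("radius must be positive")
    if crick.orientation not in ("parallel", "antiparallel"):
        raise ValueError(f"unknown orientation {crick.orientation!r}")
    if crick.handedness not in ("left", "right"):
        raise ValueError(f"unknown handedness {crick.handedness!r}")
    implied = "parallel" if chi < 90.0 else "antiparallel"
    if chi == 90.0:
        raise ValueError("chi = 90 deg leaves the orientation undefined; infeasible")
    if implied != crick.orientation:
        raise ValueError(
            f"infeasible parameters: chi = {chi} deg between directed axes implies "
            f"{implied}, but orientation {crick.orientation!r} was requested"
        )

    signed = -chi if crick.handedness == "right" else chi
    half = math.radians(signed / 2.0)
    # axes lie in planes x = ±radius; common normal is +x (A -> B)
    u_a = np.array([0.0, math.sin(half), math.cos(half)])
    u_b = np.array([0.0, -math.sin(half), math.cos(half)])

    frames = []
    for seq, chain, u, xoff, first in (
        (seq_a, "A", u_a, -crick.radius, 1),
        (seq_b, "B", u_b, +crick.radius, 1001),
    ):
        helix = build_ideal_helix(seq, chain=chain, first_resid=first)
        ca = helix.coords[helix.select(names=["CA"])]
        axis = fit_helix_axis(ca)
        R = _rotation_aligning(axis.direction, u)
        shifted = (helix.coords - axis.point) @ R.T + np.array([xoff, 0.0, 0.0])
        frames.append(Frame(helix.atoms, shifted))

    atoms = tuple(frames[0].atoms) + tuple(frames[1].atoms)
    coords = np.concatenate([frames[0].coords, frames[1].coords])
    return Frame(atoms, coords)


# --------------------------------------------------------------------------
# trajectories with planted interactions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSpec:
    chain: str
    resid: int
    name: str
    icode: str = ""


@dataclass
class InteractionSchedule:
    """On/off plan for one donor–acceptor pair across the trajectory.

    Give either an explicit per-frame ``presence`` vector or a target
    ``occupancy`` fraction (Bernoulli per frame, drawn from the trajectory
    seed).  In ON frames the acceptor is placed to satisfy the H-bond
    criterion (distance in [2.7, 3.4] Å, off-axis angle < 25°); in OFF frames
    the pair is kept > 5 Å apart.
    """

    donor: AtomSpec
    acceptor: AtomSpec
    presence: Sequence[bool] | None = None
    occupancy: float | None = None
    off_distance: float = 6.0   # Å enforced in OFF frames (> 5 breaks the H-bond
                                # criterion; use > 6.5 to also break a salt bridge)

    def __post_init__(self):
        if (self.presence is None) == (self.occupancy is None):
            raise ValueError("give exactly one of presence / occupancy")
        if self.occupancy is not None and not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        if self.off_distance <= 5.0:
            raise ValueError("off_distance must exceed 5 Å")


@dataclass(frozen=True)
class NoiseModel:
    """Isotropic per-residue Gaussian coordinate noise (Å standard deviation)."""

    sigma: float = 0.0
    per_residue: Mapping[ResidueKey, float] | None = None

    def atom_sigmas(self, frame: Frame) -> np.ndarray:
        out = np.full(frame.n_atoms, float(self.sigma))
        if self.per_residue:
            for i, a in enumerate(frame.atoms):
                if a.residue_key in self.per_residue:
                    out[i] = float(self.per_residue[a.residue_key])
        if np.any(out < 0):
            raise ValueError("sigma must be >= 0")
        return out


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (v * math.cos(angle)
            + np.cross(axis, v) * math.sin(angle)
            + axis * np.dot(axis, v) * (1 - math.cos(angle)))


def generate_trajectory(
    base: Frame,
    noise: NoiseModel,
    schedules: Sequence[InteractionSchedule] = (),
    n_frames: int = 50,
    seed: int = 0,
    dt: float = 50.0,
    discard_prefix: int = 0,
) -> Trajectory:
    """Base structure + Gaussian noise + enforced interaction schedules.

    Noise is applied first, then each ON-frame pair geometry is enforced, so
    planted interactions always pass the detector regardless of noise draw.
    Bit-identical output for identical seeds.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    sigmas = noise.atom_sigmas(base)
    coords = base.coords[None, :, :] + rng.standard_normal(
        (n_frames, base.n_atoms, 3)) * sigmas[None, :, None]

    # resolve schedules; the acceptor atom is the one moved to enforce geometry
    annotation = annotate_chemistry(base)
    donor_h = {d.atom: d.hydrogens for d in annotation.donors}
    moved: dict[int, int] = {}
    plans = []
    for s_idx, sched in enumerate(schedules):
        di = base.atom_index(sched.donor.chain, sched.donor.resid,
                             sched.donor.name, sched.donor.icode)
        ai = base.atom_index(sched.acceptor.chain, sched.acceptor.resid,
                             sched.acceptor.name, sched.acceptor.icode)
        if ai in moved or ai == di:
            raise ValueError(
                f"conflicting schedules: atom {base.atoms[ai].label()} is "
                f"shared between schedules {moved.get(ai)} and {s_idx}"
            )
        for other_di, *_ in plans:
            if ai == other_di:
                raise ValueError("schedule acceptor collides with another schedule's donor")
        moved[ai] = s_idx
        if sched.presence is not None:
            presence = np.asarray(sched.presence, bool)
            if presence.shape != (n_frames,):
                raise ValueError(
                    f"presence vector length {presence.shape[0]} != n_frames {n_frames}")
        else:
            presence = rng.random(n_frames) < sched.occupancy
        plans.append((di, ai, presence, sched.off_distance))

    for di, ai, presence, off_distance in plans:
        hs = donor_h.get(di, ())
        for f in range(n_frames):
            d = coords[f, di]
            if hs:
                u = _unit(coords[f, hs[0]] - d)
            else:
                a = coords[f, ai]
                u = _unit(a - d) if np.linalg.norm(a - d) > 1e-9 else np.array([0.0, 0.0, 1.0])
            if presence[f]:
                r = rng.uniform(2.7, 3.4)
                alpha = math.radians(rng.uniform(0.0, 20.0))
                phi = rng.uniform(0.0, 2 * math.pi)
                perp_raw = np.cross(u, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp_raw) < 1e-8:
                    perp_raw = np.cross(u, [0.0, 1.0, 0.0])
                perp = _rotate_about(_unit(perp_raw), u, phi)
                direction = _rotate_about(u, perp, alpha)
                coords[f, ai] = d + r * direction
            else:
                a = coords[f, ai]
                sep = np.linalg.norm(a - d)
                if sep < off_distance:
                    direction = _unit(a - d) if sep > 1e-9 else u
                    coords[f, ai] = d + off_distance * direction

    return Trajectory(base.atoms, coords, dt=dt, discard_prefix=discard_prefix)


# --------------------------------------------------------------------------
# mock membrane
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SlabGeometry:
    z_head: float = -15.0       # Å, head-group plane
    spacing: float = 8.0        # Å, in-plane lipid grid spacing
    origin: tuple[float, float] = (0.0, 0.0)


def build_membrane_mock(
    n_pc: int,
    n_pe: int,
    slab: SlabGeometry = SlabGeometry(),
    seed: int = 0,
    chain: str = "L",
    first_resid: int = 1,
) -> Frame:
    """Slab of coarse pseudo-lipids with real head-group H-bond chemistry.

    Each lipid is a head group (N; P-ester oxygens O13/O14) plus two tail
    beads.  POPE carries an amine donor (N with HN1–HN3); POPC's quaternary N
    has no hydrogens and cannot donate.  Species alternate across the grid.
    Not a physical membrane — only the chemistry matters downstream.
    """
    if n_pc < 0 or n_pe < 0:
        raise ValueError("lipid counts must be >= 0")
    n_total = n_pc + n_pe
    rng = np.random.default_rng(seed)
    species = []
    pc_left, pe_left = n_pc, n_pe
    for i in range(n_total):
        if pc_left and (i % 2 == 0 or not pe_left):
            species.append("PC")
            pc_left -= 1
        else:
            species.append("PE")
            pe_left -= 1

    side = max(1, math.ceil(math.sqrt(max(n_total, 1))))
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = 0
    for i, resname in enumerate(species):
        gx, gy = i % side, i // side
        x0 = slab.origin[0] + gx * slab.spacing + rng.uniform(-0.3, 0.3)
        y0 = slab.origin[1] + gy * slab.spacing + rng.uniform(-0.3, 0.3)
        z0 = slab.z_head
        resid = first_resid + i
        lipid_atoms = [
            ("N", "N", np.array([x0, y0, z0 + 2.0])),
            ("P", "P", np.array([x0 + 0.8, y0, z0])),
            ("O13", "O", np.array([x0 + 1.6, y0 + 0.8, z0])),
            ("O14", "O", np.array([x0 + 1.6, y0 - 0.8, z0])),
            ("C1", "C", np.array([x0, y0 + 0.4, z0 - 3.0])),
            ("C2", "C", np.array([x0, y0 - 0.4, z0 - 6.0])),
        ]
        if resname == "PE":
            for j, hname in enumerate(("HN1", "HN2", "HN3")):
                ang = 2 * math.pi * j / 3.0
                lipid_atoms.append(
                    (hname, "H",
                     np.array([x0 + 0.5 * math.cos(ang), y0 + 0.5 * math.sin(ang),
                               z0 + 2.85]))
                )
        for name, element, pos in lipid_atoms:
            serial += 1
            records.append(AtomRecord(serial, name, element, resname, resid, chain))
            coords.append(pos)
    if not records:
        raise ValueError("empty membrane (no lipids)")
    return Frame(records, np.asarray(coords))


# --------------------------------------------------------------------------
# synthetic nucleotide-binding pocket
# --------------------------------------------------------------------------

_POCKET_DONORS = [
    # (resname, donor atom) cycled over the planted contacts; mirrors the
    # chemistry of a P-loop pocket (backbone amides, Ser/Thr hydroxyls, Lys)
    ("ASN", "ND2"), ("THR", "OG1"), ("GLY", "N"), ("LYS", "NZ"),
    ("SER", "OG"), ("ALA", "N"), ("LYS", "NZ"), ("LYS", "NZ"),
    ("ASP", "N"), ("GLY", "N"), ("HIS", "NE2"), ("GLU", "N"),
]

_GDP_ACCEPTORS = ["O1B", "O2B", "O3B", "O1A", "O2A", "O3A",
                  "O5'", "O4'", "O2'", "O3'", "O6", "N7", "N3"]


def build_nucleotide_pocket(n_contacts: int = 10, seed: int = 0,
                            first_resid: int = 190) -> Frame:
    """SYNTHETIC nucleotide pocket: a GDP molecule ringed by protein donors.

    This is a constructed stand-in for a crystal-structure binding site, not a
    real pocket: exactly ``n_contacts`` protein-donor → GDP-acceptor pairs sit
    at 2.9 Å (heavy-atom), every other cross pair is kept > 4.5 Å, so the
    heavy-atom 3.5 Å network-size count is ``n_contacts`` by construction.
    """
    if not (1 <= n_contacts <= min(len(_POCKET_DONORS), len(_GDP_ACCEPTORS))):
        raise ValueError(f"n_contacts must be in [1, {len(_GDP_ACCEPTORS)}]")
    rng = np.random.default_rng(seed)
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    serial = [0]

    def add(name, element, resname, resid, chain, pos):
        serial[0] += 1
        records.append(AtomRecord(serial[0], name, element, resname, resid, chain))
        coords.append(np.asarray(pos, float))

    # GDP acceptors spread on a wide ring so planted pairs are isolated
    ring_r = 9.0
    gdp_positions = {}
    for k, aname in enumerate(_GDP_ACCEPTORS):
        ang = 2 * math.pi * k / len(_GDP_ACCEPTORS)
        pos = np.array([ring_r * math.cos(ang), ring_r * math.sin(ang),
                        0.4 * math.sin(3 * ang)])
        gdp_positions[aname] = pos
        add(aname, aname[0], "GDP", 901, "X", pos)
    # remaining GDP scaffold atoms (phosphorus, anomeric carbon, the base's
    # N1/N2 donors) near the centre, well inside the acceptor ring
    add("PA", "P", "GDP", 901, "X", np.array([0.0, 0.0, 1.5]))
    add("PB", "P", "GDP", 901, "X", np.array([1.5, 0.0, 1.5]))
    add("C1'", "C", "GDP", 901, "X", np.array([0.0, 0.0, -1.5]))
    add("N1", "N", "GDP", 901, "X", np.array([-1.2, 0.8, -1.0]))
    add("N2", "N", "GDP", 901, "X", np.array([-2.2, 1.6, -1.2]))

    for k in range(n_contacts):
        resname, donor_name = _POCKET_DONORS[k]
        resid = first_resid + k
        target = gdp_positions[_GDP_ACCEPTORS[k]]
        outward = _unit(target - np.array([0.0, 0.0, target[2]])
                        if np.linalg.norm(target[:2]) > 1e-9 else np.array([1.0, 0.0, 0.0]))
        dpos = target + 2.9 * outward
        # backbone scaffolding behind the donor, pointing further out
        n_pos = dpos if donor_name == "N" else dpos + 1.9 * outward
        ca = n_pos + 1.46 * outward + np.array([0.0, 0.0, 0.6])
        c = ca + 1.52 * outward
        o = c + 1.23 * np.array([0.0, 0.0, 1.0])
        add("N", "N", resname, resid, "A", n_pos)
        add("CA", "C", resname, resid, "A", ca)
        add("C", "C", resname, resid, "A", c)
        add("O", "O", resname, resid, "A", o)
        if donor_name != "N":
            add("CB", "C", resname, resid, "A", ca + 1.4 * np.array([0.0, 0.0, 1.0]))
            add(donor_name, donor_name[0], resname, resid, "A", dpos)
    return Frame(records, np.asarray(coords) + rng.normal(0.0, 1e-4, (len(records), 3)))
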