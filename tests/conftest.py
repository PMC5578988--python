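"""Shared fixtures: synthetic structures and independent reference oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from helixdyn.core import Frame

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from helixdyn.synthetic_data import (build_antiparallel_sheet, build_ideal_helix,
                                     build_membrane_mock)


@pytest.fixture(scope="session")
def helix15() -> Frame:
    return build_ideal_helix("A" * 15)


@pytest.fixture(scope="session")
def helix_mixed() -> Frame:
    return build_ideal_helix("AKESLAKESLAKESL")


@pytest.fixture(scope="session")
def sheet() -> Frame:
    return build_antiparallel_sheet("AGAGAGA")


def strip_hydrogens(frame: Frame) -> Frame:
    idx = [i for i, a in enumerate(frame.atoms) if a.element != "H"]
    return Frame([frame.atoms[i] for i in idx], frame.coords[idx])


def to_mdtraj(frame: Frame):
    """Convert a Frame to an mdtraj.Trajectory (for the reference DSSP)."""
    import mdtraj as md

    top = md.Topology()
    chains: dict = {}
    residues: dict = {}
    for a in frame.atoms:
        if a.chain not in chains:
            chains[a.chain] = top.add_chain()
        rk = (a.chain, a.resid, a.icode)
        if rk not in residues:
            residues[rk] = top.add_residue(a.resname, chains[a.chain],
                                           resSeq=a.resid)
        try:
            elem = md.element.get_by_symbol(a.element)
        except KeyError:
            elem = md.element.virtual
        top.add_atom(a.name, elem, residues[rk])
    return md.Trajectory(frame.coords[None] / 10.0, top)


def reference_dssp(frame: Frame) -> str:
    """Independent oracle: mdtraj's built-in DSSP, '-' for loop/NA."""
    import mdtraj as md

    codes = md.compute_dssp(to_mdtraj(frame), simplified=False)[0]
    return "".join("-" if c in (" ", "", "C", "NA") else c for c in codes)


# ---------------------------------------------------------------------------
# brute-force detector oracles (independent of the package implementations)
# ---------------------------------------------------------------------------

def brute_force_hbonds(frame: Frame, annotation, dist_cutoff=3.5,
                       angle_cutoff=30.0) -> set[tuple[int, int]]:
    """All-pairs O(n^2) H-bond reference: returns (donor, acceptor) pairs."""
    pairs = set()
    for donor in annotation.donors:
        di = donor.atom
        for ai in annotation.acceptors:
            ai = int(ai)
            if ai == di:
                continue
            if frame.atoms[di].residue_key == frame.atoms[ai].residue_key:
                continue
            d = float(np.linalg.norm(frame.coords[ai] - frame.coords[di]))
            if d > dist_cutoff + 1e-9:
                continue
            if annotation.mode == "heavy_only":
                pairs.add((di, ai))
                continue
            if not donor.hydrogens:
                continue
            for hi in donor.hydrogens:
                u = frame.coords[hi] - frame.coords[di]
                v = frame.coords[ai] - frame.coords[di]
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if ang <= angle_cutoff + 1e-9:
                    pairs.add((di, ai))
                    break
    return pairs


def brute_force_salt_bridges(frame: Frame, annotation, cutoff=6.5):
    """All-pairs salt-bridge reference: (negative residue, positive residue)."""
    out = set()
    for gn in annotation.charged_groups:
        if gn.sign >= 0:
            continue
        for gp in annotation.charged_groups:
            if gp.sign <= 0:
                continue
            dmin = min(
                float(np.linalg.norm(frame.coords[i] - frame.coords[j]))
                for i in gn.atoms for j in gp.atoms
            )
            if dmin <= cutoff + 1e-9:
                out.add((gn.residue, gp.residue))
    return out


def brute_force_gromos(matrix: np.ndarray, cutoff: float):
    """Plain-python greedy neighbour-count clustering (same published rule).

    Returns [(center, sorted members)] with the package's tie-breaks: lowest
    index wins equal neighbour counts; output ordered by (-size, center).
    """
    n = matrix.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_center, best_members = None, None
        for c in sorted(remaining):
            members = [m for m in sorted(remaining) if matrix[c, m] <= cutoff]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = c, members
        clusters.append((best_center, sorted(best_members)))
        remaining -= set(best_members)
    clusters.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    return clusters


def random_mixed_frame(rng: np.random.Generator, n_residues: int = 40) -> Frame:
    """A disordered frame with protein + lipid + ligand chemistry, ≤ ~500 atoms.

    Coordinates are uniform in a 25 Å box, so H-bond/salt-bridge candidates at
    every distance regime (including near the cutoffs) occur by chance.
    """
    from helixdyn.synthetic_data import build_ideal_helix

    seq = "".join(rng.choice(list("AKESDTRNQ")) for _ in range(n_residues))
    base = build_ideal_helix(seq)
    mem = build_membrane_mock(3, 3, seed=int(rng.integers(2**31)))
    atoms = list(base.atoms) + [
        a.__class__(a.serial + base.n_atoms, a.name, a.element, a.resname,
                    a.resid, a.chain, a.icode)
        for a in mem.atoms
    ]
    n = len(atoms)
    coords = rng.uniform(0.0, 25.0, (n, 3))
    # keep each donor's hydrogens chemically adjacent to the heavy atom
    frame = Frame(atoms, coords)
    from helixdyn.structure_io import annotate_chemistry
    ann = annotate_chemistry(frame)
    for d in ann.donors:
        for hi in d.hydrogens:
            coords[hi] = coords[d.atom] + rng.normal(0, 0.4, 3) * 0.5 + \
                np.array([1.0, 0.0, 0.0]) * 0.5
    return Frame(atoms, coords)
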