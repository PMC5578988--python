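"""Kabsch–Sander secondary-structure assignment and per-residue persistence.

The assignment reproduces the DSSP scheme: backbone H-bonds are scored with
the electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and accepted below -0.5 kcal/mol; n-turn and bridge patterns over the bond
network yield the eight states H, G, I, E, B, T, S and '-'.  The amide H is
taken from the structure when present, otherwise reconstructed in the peptide
plane anti to the preceding carbonyl (the Kabsch–Sander convention).  All
criteria are inter-atomic distances, so the assignment is invariant under
rigid-body motion of the frame.

π-helix is given priority over α when both patterns match (the modern DSSP
dialect); pass ``pi_over_h=False`` for the classic ordering.  The two
dialects only differ on structures that actually contain π patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Frame, ResidueKey, Trajectory

__all__ = [
    "SecStructMap",
    "assign_secstruct",
    "backbone_hbond_energies",
    "persistence_from_assignments",
    "persistence_map",
]

_Q = 0.084 * 332.0          # kcal/mol * Å
_EBOND = -0.5               # kcal/mol acceptance threshold
_CODE_PRIORITY = "HEBGITS-"  # for dominant-code tie-breaks


@dataclass
class _Backbone:
    key: ResidueKey
    chain: str
    n: np.ndarray | None
    ca: np.ndarray | None
    c: np.ndarray | None
    o: np.ndarray | None
    h: np.ndarray | None
    is_pro: bool
    complete: bool


def _collect_backbone(frame: Frame) -> list[_Backbone]:
    out: list[_Backbone] = []
    protein = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
    for key, resname, idxs in frame.residues():
        if resname not in protein:
            continue
        by_name = {frame.atoms[i].name: i for i in idxs}
        def pos(name):
            return frame.coords[by_name[name]] if name in by_name else None
        h = None
        for hname in ("H", "HN"):
            if hname in by_name:
                h = frame.coords[by_name[hname]]
                break
        bb = _Backbone(
            key=key, chain=key.chain,
            n=pos("N"), ca=pos("CA"), c=pos("C"), o=pos("O"), h=h,
            is_pro=(resname == "PRO"),
            complete=all(pos(x) is not None for x in ("N", "CA", "C", "O")),
        )
        out.append(bb)
    return out


def backbone_hbond_energies(frame: Frame) -> tuple[list[ResidueKey], np.ndarray]:
    """Kabsch–Sander energies E[i, j] for donor NH(i) -> acceptor C=O(j).

    Entries are +inf where no bond is possible (incomplete backbone, proline
    donor without explicit H, same or peptide-bonded residue pair).
    """
    bbs = _collect_backbone(frame)
    n = len(bbs)
    E = np.full((n, n), np.inf)
    # reconstruct missing amide H anti to the preceding carbonyl
    hpos: list[np.ndarray | None] = []
    for i, bb in enumerate(bbs):
        if bb.h is not None:
            hpos.append(bb.h)
            continue
        if bb.is_pro or bb.n is None:
            hpos.append(None)
            continue
        prev = bbs[i - 1] if i > 0 else None
        if (prev is not None and prev.chain == bb.chain and prev.complete):
            d = prev.c - prev.o
            hpos.append(bb.n + d / np.linalg.norm(d))
        else:
            hpos.append(None)
    for i, bb_i in enumerate(bbs):          # donor
        if bb_i.n is None or hpos[i] is None:
            continue
        for j, bb_j in enumerate(bbs):      # acceptor
            if not bb_j.complete or j == i:
                continue
            if bb_i.chain == bb_j.chain and i - j == 1:
                continue  # donor bonded to its own preceding carbonyl
            r_on = np.linalg.norm(bb_j.o - bb_i.n)
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(bb_j.c - hpos[i])
            r_oh = np.linalg.norm(bb_j.o - hpos[i])
            r_cn = np.linalg.norm(bb_j.c - bb_i.n)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                E[i, j] = -9.9  # clash-level contact, treat as strong bond
                continue
            E[i, j] = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return [bb.key for bb in bbs], E


def _bond_matrix(E: np.ndarray) -> np.ndarray:
    """Boolean donor->acceptor bonds: E < -0.5, best two acceptors per donor."""
    n = E.shape[0]
    bonds = np.zeros((n, n), bool)
    for i in range(n):
        order = np.argsort(E[i])[:2]
        for j in order:
            if E[i, j] < _EBOND:
                bonds[i, j] = True
    return bonds


def assign_secstruct(frame: Frame, pi_over_h: bool = True) -> dict[ResidueKey, str]:
    """Per-residue Kabsch–Sander code over the protein residues of a frame.

    Residues missing backbone atoms are coded '-' (with a warning); isolated
    residues without bonded neighbours come out '-' naturally.
    """
    keys, E = backbone_hbond_energies(frame)
    bbs = _collect_backbone(frame)
    n = len(keys)
    if n == 0:
        return {}
    for bb in bbs:
        if not bb.complete:
            warnings.warn(f"residue {bb.key} missing backbone atoms; coded '-'")
    # acc(i, j): C=O of i accepts from N-H of j  (Kabsch-Sander Hbond(i, j))
    bonds = _bond_matrix(E)
    same_chain = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(n):
            same_chain[i, j] = bbs[i].chain == bbs[j].chain

    def acc(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and bonds[j, i]

    # n-turns: CO(i) accepts from NH(i+n), same chain, no chain break between
    turns = {k: np.zeros(n, bool) for k in (3, 4, 5)}
    for k in turns:
        for i in range(n - k):
            if same_chain[i, i + k] and acc(i, i + k):
                turns[k][i] = True

    helix = {k: np.zeros(n, bool) for k in (3, 4, 5)}
    for k in turns:
        for i in range(1, n - k):
            if turns[k][i - 1] and turns[k][i]:
                helix[k][i:i + k] = True

    # bridges
    para = np.zeros((n, n), bool)
    anti = np.zeros((n, n), bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if not same_chain[i, j]:
                pass  # inter-chain bridges allowed
            if (acc(i - 1, j) and acc(j, i + 1)) or (acc(j - 1, i) and acc(i, j + 1)):
                para[i, j] = para[j, i] = True
            if (acc(i, j) and acc(j, i)) or (acc(i - 1, j + 1) and acc(j - 1, i + 1)):
                anti[i, j] = anti[j, i] = True

    is_e = np.zeros(n, bool)
    is_b = np.zeros(n, bool)
    bridge_partners: dict[int, list[int]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if para[i, j] or anti[i, j]:
                bridge_partners.setdefault(i, []).append(j)
                bridge_partners.setdefault(j, []).append(i)
    # ladders: consecutive bridges of the same type
    in_ladder = np.zeros(n, bool)
    for i in range(n - 1):
        for j in range(n - 1):
            if para[i, j] and para[i + 1, j + 1]:
                in_ladder[[i, i + 1, j, j + 1]] = True
            if j >= 1 and anti[i, j] and anti[i + 1, j - 1]:
                in_ladder[[i, i + 1, j, j - 1]] = True
    for i in bridge_partners:
        if in_ladder[i]:
            is_e[i] = True
        else:
            is_b[i] = True

    # turns (T): residues strictly inside an n-turn pattern
    is_t = np.zeros(n, bool)
    for k in turns:
        for i in np.nonzero(turns[k])[0]:
            is_t[i + 1:i + k] = True

    # bend (S): kappa > 70 degrees
    is_s = np.zeros(n, bool)
    for i in range(2, n - 2):
        if not (same_chain[i - 2, i] and same_chain[i, i + 2]):
            continue
        if not (bbs[i - 2].ca is not None and bbs[i].ca is not None
                and bbs[i + 2].ca is not None):
            continue
        u = bbs[i].ca - bbs[i - 2].ca
        v = bbs[i + 2].ca - bbs[i].ca
        cosk = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosk, -1, 1))) > 70.0:
            is_s[i] = True

    # overwrite from lowest to highest priority
    codes = np.full(n, "-", dtype="U1")
    low_to_high = ["S", "T", "I", "G", "E", "B", "H"]
    if pi_over_h:
        low_to_high = ["S", "T", "G", "E", "B", "H", "I"]
    flag_of = {"S": is_s, "T": is_t, "G": helix[3], "H": helix[4], "I": helix[5],
               "E": is_e, "B": is_b}
    for code in low_to_high:
        codes[flag_of[code]] = code
    for i, bb in enumerate(bbs):
        if not bb.complete:
            codes[i] = "-"
    return {key: str(codes[i]) for i, key in enumerate(keys)}


# --------------------------------------------------------------------------
# persistence over a trajectory
# --------------------------------------------------------------------------

@dataclass
class SecStructMap:
    """Per-frame codes and per-residue dominant-code persistence."""

    residues: list[ResidueKey]
    per_frame: list[str]                 # one code string per analyzed frame
    dominant: dict[ResidueKey, str]
    persistence: dict[ResidueKey, float]  # fraction of analyzed frames
    threshold: float
    stable: set[ResidueKey]              # persistence >= threshold (inclusive)

    def to_rows(self) -> list[tuple[str, int, str, str, float]]:
        return [
            (k.chain, k.resid, k.icode, self.dominant[k], self.persistence[k])
            for k in self.residues
        ]


def persistence_from_assignments(
    assignments: Sequence[dict[ResidueKey, str]], threshold: float
) -> SecStructMap:
    """Aggregate per-frame code assignments into a persistence map.

    The stable set contains residues whose dominant code persists in at least
    ``threshold`` of the frames (inclusive comparison: a residue at exactly
    the threshold counts as stable).  Dominance ties break toward the
    higher-priority code (H > E > B > G > I > T > S > '-').
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if len(assignments) < 2:
        raise ValueError("persistence map needs >= 2 analyzed frames")
    residues = list(assignments[0].keys())
    counts: dict[ResidueKey, dict[str, int]] = {k: {} for k in residues}
    rows: list[str] = []
    for assignment in assignments:
        rows.append("".join(assignment[k] for k in residues))
        for k in residues:
            c = assignment[k]
            counts[k][c] = counts[k].get(c, 0) + 1
    n_frames = len(rows)
    dominant: dict[ResidueKey, str] = {}
    persistence: dict[ResidueKey, float] = {}
    for k in residues:
        best = max(counts[k].items(),
                   key=lambda kv: (kv[1], -_CODE_PRIORITY.index(kv[0])))
        dominant[k] = best[0]
        persistence[k] = best[1] / n_frames
    stable = {k for k in residues if persistence[k] >= threshold}
    return SecStructMap(residues=residues, per_frame=rows, dominant=dominant,
                        persistence=persistence, threshold=threshold, stable=stable)


def persistence_map(
    traj: Trajectory, threshold: float = 0.90, pi_over_h: bool = True
) -> SecStructMap:
    """Dominant secondary-structure persistence over the analyzed frames."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    assignments = [assign_secstruct(frame, pi_over_h=pi_over_h)
                   for _, frame in traj.analyzed_frames()]
    return persistence_from_assignments(assignments, threshold)
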