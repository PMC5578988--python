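"""Heptad registers, register-typed salt bridges and (small)xxx(small) motifs.

The heptad register (positions a–g, with a/d the canonical hydrophobic core)
is supplied by the user as an anchor residue plus its letter and propagated
by modular arithmetic — register *prediction* is out of scope.  Salt bridges
are typed by the register positions of their residues ("b-e" denotes an
i→i+3 bridge between those positions); the intrahelical b-e census mirrors
the organization seen in coiled-coil bundles such as the SNARE complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import ResidueKey
from .interactions import SaltBridgeEvent

__all__ = [
    "HeptadRegister",
    "RegisterTypedBridge",
    "MotifHit",
    "assign_register",
    "classify_bridge_register",
    "register_census",
    "scan_small_xxx_small",
]

_HEPTAD = "abcdefg"


@dataclass(frozen=True)
class HeptadRegister:
    """Heptad positions over one helical segment (author resid range)."""

    helix_id: str
    chain: str
    start: int
    end: int                     # inclusive
    anchor: int
    anchor_position: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"empty segment {self.start}-{self.end}")
        if not (self.start <= self.anchor <= self.end):
            raise ValueError(
                f"anchor {self.anchor} outside segment {self.start}-{self.end}")
        if self.anchor_position not in _HEPTAD:
            raise ValueError(f"anchor position must be one of a-g, "
                             f"got {self.anchor_position!r}")

    def position(self, resid: int) -> str:
        """Heptad letter of a residue in the segment (cyclic from anchor)."""
        if not (self.start <= resid <= self.end):
            raise KeyError(f"residue {resid} outside segment "
                           f"{self.start}-{self.end} of {self.helix_id}")
        off = _HEPTAD.index(self.anchor_position) + (resid - self.anchor)
        return _HEPTAD[off % 7]

    def covers(self, key: ResidueKey) -> bool:
        return key.chain == self.chain and self.start <= key.resid <= self.end


def assign_register(
    helix_id: str,
    chain: str,
    start: int,
    end: int,
    anchor: int,
    anchor_position: str = "a",
) -> HeptadRegister:
    """Build the register of a segment from an anchored position."""
    return HeptadRegister(helix_id=helix_id, chain=chain, start=start, end=end,
                          anchor=anchor, anchor_position=anchor_position)


@dataclass(frozen=True)
class RegisterTypedBridge:
    bridge: SaltBridgeEvent
    register_pair: str           # e.g. "b-e" (canonical alphabetic order)
    scope: str                   # 'intrahelical' | 'interhelical' | 'unregistered'
    helices: tuple[str, ...]     # helix id(s) involved


def classify_bridge_register(
    bridge: SaltBridgeEvent,
    registers: Sequence[HeptadRegister],
) -> RegisterTypedBridge:
    """Type a salt bridge by the heptad positions of its two residues.

    Intrahelical pairs report the canonical alphabetic pair string ("b-e",
    never "e-b"); interhelical pairs report "helixA:pos-helixB:pos" ordered
    by helix id.  A residue outside every register yields scope
    'unregistered'.
    """
    found: list[tuple[HeptadRegister, str]] = []
    for key in (bridge.negative, bridge.positive):
        reg = next((r for r in registers if r.covers(key)), None)
        if reg is None:
            return RegisterTypedBridge(bridge, "", "unregistered", ())
        found.append((reg, reg.position(key.resid)))
    (reg_a, pos_a), (reg_b, pos_b) = found
    if reg_a.helix_id == reg_b.helix_id:
        pair = "-".join(sorted([pos_a, pos_b]))
        return RegisterTypedBridge(bridge, pair, "intrahelical", (reg_a.helix_id,))
    items = sorted([(reg_a.helix_id, pos_a), (reg_b.helix_id, pos_b)])
    pair = f"{items[0][0]}:{items[0][1]}-{items[1][0]}:{items[1][1]}"
    return RegisterTypedBridge(bridge, pair, "interhelical",
                               (items[0][0], items[1][0]))


def register_census(
    bridges: Iterable[SaltBridgeEvent],
    registers: Sequence[HeptadRegister],
) -> dict[tuple[str, str], int]:
    """Count bridges by (scope, register pair) for census tables."""
    out: dict[tuple[str, str], int] = {}
    for b in bridges:
        typed = classify_bridge_register(b, registers)
        key = (typed.scope, typed.register_pair)
        out[key] = out.get(key, 0) + 1
    return out


# --------------------------------------------------------------------------
# (small)xxx(small) motifs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    start: int                   # author resid of the first small residue
    end: int                     # start + 4
    pattern: str                 # matched subsequence, e.g. "GVVAG"
    motif_class: str             # 'GxxxG' | '(small)xxx(small)'


def scan_small_xxx_small(
    sequence: str,
    small: Iterable[str] = ("G", "A", "S"),
    offset: int = 1,
) -> list[MotifHit]:
    """All i, i+4 pairs of small residues (one helix face apart).

    Overlapping hits are all reported; GxxxG pairs are flagged as their own
    class (the canonical dimerization motif) within the general
    (small)xxx(small) family.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    small_set = {s.upper() for s in small}
    hits: list[MotifHit] = []
    for i in range(len(sequence) - 4):
        a, b = sequence[i], sequence[i + 4]
        if a in small_set and b in small_set:
            cls = "GxxxG" if (a == "G" and b == "G") else "(small)xxx(small)"
            hits.append(MotifHit(start=offset + i, end=offset + i + 4,
                                 pattern=sequence[i:i + 5], motif_class=cls))
    return hits
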