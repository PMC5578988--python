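"""Core in-memory containers: atoms, frames and trajectories.

Residue identity is the *author* numbering read from the input file
(chain id + residue number + insertion code).  An internal dense 0-based
atom index exists for array work but never appears in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "Frame",
    "Trajectory",
    "Selection",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom's identity. Coordinates live in the owning Frame/Trajectory."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str = "A"
    icode: str = ""

    @property
    def residue_key(self) -> "ResidueKey":
        return ResidueKey(self.chain, self.resid, self.icode)

    def label(self) -> str:
        """Human-readable label, e.g. ``A:LYS716:NZ``."""
        return f"{self.chain}:{self.resname}{self.resid}{self.icode}:{self.name}"


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbering identity of a residue."""

    chain: str
    resid: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}:{self.resid}{self.icode}"


class Frame:
    """A single structure: an ordered atom table plus an (n, 3) coordinate array (Å)."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        coords: np.ndarray,
        time: float | None = None,
        box: np.ndarray | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(atoms)} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.coords = coords
        self.time = time
        self.box = None if box is None else np.asarray(box, dtype=float)
        self._index: dict[tuple[str, int, str, str], int] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # -- lookup ---------------------------------------------------------

    def _build_index(self) -> dict[tuple[str, int, str, str], int]:
        if self._index is None:
            idx: dict[tuple[str, int, str, str], int] = {}
            for i, a in enumerate(self.atoms):
                key = (a.chain, a.resid, a.icode, a.name)
                if key in idx:
                    raise ValueError(f"duplicate atom {a.label()} in frame")
                idx[key] = i
            self._index = idx
        return self._index

    def atom_index(self, chain: str, resid: int, name: str, icode: str = "") -> int:
        """Dense index of an atom by author identity; KeyError if absent."""
        try:
            return self._build_index()[(chain, resid, icode, name)]
        except KeyError:
            raise KeyError(f"atom {chain}:{resid}{icode}:{name} not in frame") from None

    def residues(self) -> list[tuple[ResidueKey, str, list[int]]]:
        """Residues in atom order: (key, resname, atom indices)."""
        out: list[tuple[ResidueKey, str, list[int]]] = []
        seen: dict[ResidueKey, int] = {}
        for i, a in enumerate(self.atoms):
            key = a.residue_key
            if key not in seen:
                seen[key] = len(out)
                out.append((key, a.resname, []))
            out[seen[key]][2].append(i)
        return out

    # -- selection ------------------------------------------------------

    def select(
        self,
        chain: str | Iterable[str] | None = None,
        resid_range: tuple[int, int] | None = None,
        resids: Iterable[int] | None = None,
        resnames: Iterable[str] | None = None,
        names: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Return dense indices of atoms matching all given filters."""
        chains = None if chain is None else ({chain} if isinstance(chain, str) else set(chain))
        resid_set = None if resids is None else set(resids)
        resname_set = None if resnames is None else set(resnames)
        name_set = None if names is None else set(names)
        keep = []
        for i, a in enumerate(self.atoms):
            if chains is not None and a.chain not in chains:
                continue
            if resid_range is not None and not (resid_range[0] <= a.resid <= resid_range[1]):
                continue
            if resid_set is not None and a.resid not in resid_set:
                continue
            if resname_set is not None and a.resname not in resname_set:
                continue
            if name_set is not None and a.name not in name_set:
                continue
            keep.append(i)
        return np.asarray(keep, dtype=int)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """New frame with coords mapped x -> R @ x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return Frame(self.atoms, self.coords @ R.T + t, time=self.time, box=self.box)


@dataclass
class Selection:
    """A named atom subset of a topology (dense indices)."""

    name: str
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError(f"selection '{self.name}' is empty")


class Trajectory:
    """Ordered frames over one shared topology.

    ``discard_prefix`` frames at the start are excluded from every statistic
    (equilibration discard); ``dt`` is the saved-frame spacing in ps.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        coords: np.ndarray,
        dt: float = 1.0,
        discard_prefix: int = 0,
        times: np.ndarray | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != len(atoms) or coords.shape[2] != 3:
            raise ValueError(
                f"coords shape {coords.shape} incompatible with {len(atoms)} atoms"
            )
        if coords.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not (0 <= discard_prefix < coords.shape[0]):
            raise ValueError(
                f"discard_prefix {discard_prefix} must be < n_frames {coords.shape[0]}"
            )
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.coords = coords
        self.dt = float(dt)
        self.discard_prefix = int(discard_prefix)
        if times is None:
            times = np.arange(coords.shape[0], dtype=float) * self.dt
        self.times = np.asarray(times, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def analyzed_indices(self) -> np.ndarray:
        """Frame indices that enter statistics (after the discard prefix)."""
        return np.arange(self.discard_prefix, self.n_frames)

    @property
    def n_analyzed(self) -> int:
        return self.n_frames - self.discard_prefix

    def frame(self, i: int) -> Frame:
        return Frame(self.atoms, self.coords[i], time=self.times[i])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def analyzed_frames(self) -> Iterator[tuple[int, Frame]]:
        for i in self.analyzed_indices:
            yield int(i), self.frame(int(i))

    def with_discard(self, discard_prefix: int) -> "Trajectory":
        return Trajectory(self.atoms, self.coords, dt=self.dt,
                          discard_prefix=discard_prefix, times=self.times)

    @staticmethod
    def from_frames(frames: Sequence[Frame], dt: float = 1.0,
                    discard_prefix: int = 0) -> "Trajectory":
        if len(frames) == 0:
            raise ValueError("no frames")
        atoms = frames[0].atoms
        for k, f in enumerate(frames):
            if len(f.atoms) != len(atoms):
                raise ValueError(f"atom count mismatch at frame {k}")
            if f.atoms != atoms:
                raise ValueError(f"atom identity mismatch at frame {k}")
        coords = np.stack([f.coords for f in frames])
        return Trajectory(atoms, coords, dt=dt, discard_prefix=discard_prefix)

    def concatenated(self, other: "Trajectory") -> "Trajectory":
        """Concatenate analyzed portions of two trajectories over one topology."""
        if self.atoms != other.atoms:
            raise ValueError("topology mismatch")
        coords = np.concatenate([
            self.coords[self.discard_prefix:],
            other.coords[other.discard_prefix:],
        ])
        return Trajectory(self.atoms, coords, dt=self.dt, discard_prefix=0)
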