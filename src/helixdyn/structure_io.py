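"""Structure and trajectory I/O plus hydrogen-bonding/charge chemistry annotation.

Reading preserves *author* residue numbering, chain ids and insertion codes:
every downstream report names residues exactly as the input file does.
PDB parsing is backed by Bio.PDB; XTC/DCD reading (optional) by MDAnalysis.
The chemistry annotation is purely name-based — it never looks at coordinates —
so it is deterministic and invariant under any motion of the structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import AtomRecord, Frame, ResidueKey, Trajectory

__all__ = [
    "StructureParseError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "ChemistryAnnotation",
    "Donor",
    "ChargedGroup",
    "annotate_chemistry",
]


class StructureParseError(ValueError):
    """Raised when an input structure file cannot be parsed."""


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

_KEPT_ALTLOCS = ("", " ", "A")


def _model_to_records(model) -> tuple[list[AtomRecord], np.ndarray]:
    records: list[AtomRecord] = []
    xyz: list[np.ndarray] = []
    for chain in model:
        for residue in chain:
            _, resid, icode = residue.id
            for atom in residue:
                if atom.get_altloc() not in _KEPT_ALTLOCS:
                    continue
                element = (atom.element or "").strip()
                if not element:
                    # fall back to the leading letter of the atom name
                    element = "".join(c for c in atom.get_name() if c.isalpha())[:1]
                records.append(
                    AtomRecord(
                        serial=atom.serial_number or len(records) + 1,
                        name=atom.get_name(),
                        element=element.capitalize(),
                        resname=residue.get_resname().strip(),
                        resid=int(resid),
                        chain=str(chain.id).strip() or "A",
                        icode=icode.strip(),
                    )
                )
                xyz.append(atom.coord)
    # PDB stores 3 decimals; round away the reader's float32 representation
    return records, np.round(np.asarray(xyz, dtype=float), 3)


def _parse_pdb(path: str | Path):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:  # malformed record
        raise StructureParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models or all(len(list(m.get_atoms())) == 0 for m in models):
        raise StructureParseError(f"{path}: no atoms found")
    return models


def read_structure(path: str | Path, format: str = "pdb") -> Frame:
    """Read a single structure (first model of a multi-model file)."""
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    models = _parse_pdb(path)
    records, xyz = _model_to_records(models[0])
    if not records:
        raise StructureParseError(f"{path}: first model contains no atoms")
    return Frame(records, xyz)


def read_trajectory(
    topology: str | Path,
    traj: str | Path | None = None,
    format: str | None = None,
    dt: float = 1.0,
    discard_prefix: int = 0,
) -> Trajectory:
    """Read an ordered trajectory.

    ``multi-model-pdb`` (default): all MODEL blocks of one file; ``xtc``/``dcd``
    read topology+trajectory through MDAnalysis.  ``dt`` (ps) comes from the
    caller/config when the format has no time metadata.
    """
    traj = topology if traj is None else traj
    if format is None:
        suffix = Path(traj).suffix.lower().lstrip(".")
        format = {"pdb": "multi-model-pdb"}.get(suffix, suffix)
    format = format.lower()

    if format in ("multi-model-pdb", "pdb"):
        models = _parse_pdb(traj)
        frames = []
        ref_records: list[AtomRecord] | None = None
        for k, model in enumerate(models):
            records, xyz = _model_to_records(model)
            if ref_records is None:
                ref_records = records
            elif len(records) != len(ref_records):
                raise StructureParseError(
                    f"atom count mismatch at frame {k}: "
                    f"{len(records)} vs {len(ref_records)}"
                )
            frames.append(xyz)
        assert ref_records is not None
        coords = np.stack(frames)
        return Trajectory(ref_records, coords, dt=dt, discard_prefix=discard_prefix)

    if format in ("xtc", "dcd"):
        import MDAnalysis as mda

        u = mda.Universe(str(topology), str(traj))
        records = [
            AtomRecord(
                serial=int(a.id) if hasattr(a, "id") else i + 1,
                name=str(a.name),
                element=str(getattr(a, "element", "") or a.name[:1]).capitalize(),
                resname=str(a.resname),
                resid=int(a.resid),
                chain=str(getattr(a, "chainID", "") or getattr(a, "segid", "A")).strip() or "A",
            )
            for i, a in enumerate(u.atoms)
        ]
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory]).astype(float)
        file_dt = getattr(u.trajectory, "dt", None)
        return Trajectory(records, coords, dt=float(file_dt or dt),
                          discard_prefix=discard_prefix)

    raise ValueError(f"unsupported trajectory format {format!r}")


# --------------------------------------------------------------------------
# writing (multi-model PDB)
# --------------------------------------------------------------------------

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _format_atom_line(a: AtomRecord, xyz: np.ndarray) -> str:
    record = "ATOM  " if a.resname in _PROTEIN_RESNAMES else "HETATM"
    name = a.name
    # PDB column convention: 1/2-letter elements start at column 14/13
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    return (
        f"{record}{a.serial % 100000:5d} {name:<4s}{'':1s}{a.resname:>3s} "
        f"{(a.chain or 'A')[:1]:1s}{a.resid:4d}{a.icode or '':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2s}"
    )


def write_structure(frame: Frame, path: str | Path) -> None:
    """Write one frame as a single-model PDB."""
    with open(path, "w") as fh:
        for a, xyz in zip(frame.atoms, frame.coords):
            fh.write(_format_atom_line(a, xyz) + "\n")
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write all frames as a multi-model PDB (coordinates at 1e-3 Å precision)."""
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"MODEL     {k + 1:4d}\n")
            for a, xyz in zip(traj.atoms, traj.coords[k]):
                fh.write(_format_atom_line(a, xyz) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# chemistry annotation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Donor:
    atom: int                      # dense index of the donor heavy atom
    hydrogens: tuple[int, ...]     # dense indices of attached hydrogens


@dataclass(frozen=True)
class ChargedGroup:
    sign: int                      # +1 or -1
    atoms: tuple[int, ...]         # dense indices of member heavy atoms
    residue: ResidueKey
    resname: str


@dataclass
class ChemistryAnnotation:
    """Per-atom H-bond and charge roles for one topology."""

    mode: str                      # 'explicit_h' or 'heavy_only'
    donors: list[Donor]
    acceptors: np.ndarray          # dense indices
    charged_groups: list[ChargedGroup]
    is_protein: np.ndarray
    is_lipid: np.ndarray
    is_ligand: np.ndarray
    is_water: np.ndarray
    unknown_residues: list[tuple[ResidueKey, str]] = field(default_factory=list)

    @property
    def donor_atoms(self) -> np.ndarray:
        return np.asarray([d.atom for d in self.donors], dtype=int)

    @property
    def acceptor_set(self) -> set[int]:
        return set(int(i) for i in self.acceptors)


# residue -> donor heavy atom -> names of its hydrogens
_DONOR_TABLE: dict[str, dict[str, tuple[str, ...]]] = {
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "CYS": {"SG": ("HG",)},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},
    "TRP": {"NE1": ("HE1",)},
    "GDP": {"N1": ("H1",), "N2": ("H21", "H22"),
            "O2'": ("HO2'",), "O3'": ("HO3'",)},
    "POPE": {"N": ("HN1", "HN2", "HN3")},
    "PE": {"N": ("HN1", "HN2", "HN3")},
}

_BACKBONE_H_NAMES = ("H", "HN", "H1", "H2", "H3")

_ACCEPTOR_TABLE: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
    "GDP": ("O6", "N7", "N3", "O1A", "O2A", "O3A", "O1B", "O2B", "O3B",
            "O5'", "O4'", "O2'", "O3'"),
    "POPC": ("O11", "O12", "O13", "O14"),
    "POPE": ("O11", "O12", "O13", "O14"),
    "PC": ("O11", "O12", "O13", "O14"),
    "PE": ("O11", "O12", "O13", "O14"),
}

# residue -> (sign, member atom names)
_CHARGE_TABLE: dict[str, tuple[int, tuple[str, ...]]] = {
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
    "LYS": (+1, ("NZ",)),
    "ARG": (+1, ("NE", "NH1", "NH2")),
}

_WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3", "TIP"}
_LIPID_RESNAMES = {"POPC", "POPE", "POPG", "POPS", "DOPC", "DOPE", "PC", "PE"}
_KNOWN_LIGANDS = {"GDP", "GTP", "GNP", "ADP", "ATP", "MG", "K", "NA", "CL"}


def annotate_chemistry(
    frame: Frame,
    mode: str = "explicit_h",
    his_protonated: bool | Iterable[ResidueKey] = False,
    include_termini: bool = False,
    custom_rules: Mapping[str, Mapping] | None = None,
) -> ChemistryAnnotation:
    """Assign donor/acceptor/charged-group roles from residue and atom names.

    ``mode='heavy_only'`` registers all N/O of known donor groups as donors
    with no attached hydrogens (for crystal structures without H); downstream
    detectors then apply the distance criterion only.  ``his_protonated`` makes
    His a +1 charged group (and removes its ring N from the acceptor set),
    either globally (True) or for a listed set of residues.  Unknown residues
    are warned about, never fatal.
    """
    if mode not in ("explicit_h", "heavy_only"):
        raise ValueError(f"unknown mode {mode!r}")

    donor_table = {k: {a: tuple(h) for a, h in v.items()} for k, v in _DONOR_TABLE.items()}
    acceptor_table = dict(_ACCEPTOR_TABLE)
    charge_table = dict(_CHARGE_TABLE)
    if custom_rules:
        for resname, rules in custom_rules.items():
            if "donors" in rules:
                donor_table[resname] = {a: tuple(h) for a, h in rules["donors"].items()}
            if "acceptors" in rules:
                acceptor_table[resname] = tuple(rules["acceptors"])
            if "charge" in rules:
                sign, members = rules["charge"]
                charge_table[resname] = (int(sign), tuple(members))

    if his_protonated is True:
        his_set: set[ResidueKey] | None = None  # None => all His
    elif his_protonated is False:
        his_set = set()
    else:
        his_set = set(his_protonated)

    n = frame.n_atoms
    is_protein = np.zeros(n, bool)
    is_lipid = np.zeros(n, bool)
    is_ligand = np.zeros(n, bool)
    is_water = np.zeros(n, bool)
    donors: list[Donor] = []
    acceptors: list[int] = []
    groups: list[ChargedGroup] = []
    unknown: list[tuple[ResidueKey, str]] = []

    residues = frame.residues()
    # chain -> residue keys in order, for terminal detection
    chain_res: dict[str, list[int]] = {}
    for ridx, (key, resname, _) in enumerate(residues):
        if resname in _PROTEIN_RESNAMES:
            chain_res.setdefault(key.chain, []).append(ridx)

    for ridx, (key, resname, idxs) in enumerate(residues):
        by_name = {frame.atoms[i].name: i for i in idxs}
        protein = resname in _PROTEIN_RESNAMES
        if protein:
            is_protein[idxs] = True
        elif resname in _LIPID_RESNAMES:
            is_lipid[idxs] = True
        elif resname in _WATER_RESNAMES:
            is_water[idxs] = True
        elif resname in _KNOWN_LIGANDS or resname in donor_table or resname in acceptor_table:
            is_ligand[idxs] = True
        else:
            unknown.append((key, resname))
            warnings.warn(f"unknown residue {resname} at {key}; no chemistry assigned")
            continue

        his_on = resname == "HIS" and (his_set is None or key in his_set)

        def _add_donor(heavy: str, hnames: Sequence[str]) -> None:
            if heavy not in by_name:
                return
            if mode == "heavy_only":
                donors.append(Donor(by_name[heavy], ()))
                return
            hs = tuple(by_name[h] for h in hnames if h in by_name)
            if hs:
                donors.append(Donor(by_name[heavy], hs))

        # backbone
        if protein:
            if resname != "PRO":
                _add_donor("N", _BACKBONE_H_NAMES)
            if "O" in by_name:
                acceptors.append(by_name["O"])
            if "OXT" in by_name:
                acceptors.append(by_name["OXT"])

        # side chain / hetero donors
        for heavy, hnames in donor_table.get(resname, {}).items():
            if resname == "HIS" and not his_on:
                # neutral His: by convention ND1 acceptor, NE2 donor (HE2 tautomer)
                if heavy == "ND1":
                    continue
            _add_donor(heavy, hnames)

        # acceptors
        for aname in acceptor_table.get(resname, ()):
            if resname == "HIS":
                if his_on:
                    continue  # doubly protonated: ring N are not acceptors
                if aname == "NE2":
                    continue  # carries the tautomer H in the neutral default
            if aname in by_name:
                acceptors.append(by_name[aname])

        # water: O is both donor and acceptor
        if resname in _WATER_RESNAMES and "O" in by_name:
            acceptors.append(by_name["O"])
            _add_donor("O", ("H1", "H2", "HW1", "HW2"))

        # charged groups
        if resname in charge_table:
            sign, members = charge_table[resname]
            present = tuple(by_name[m] for m in members if m in by_name)
            if present:
                groups.append(ChargedGroup(sign, present, key, resname))
        if his_on:
            present = tuple(by_name[m] for m in ("ND1", "NE2") if m in by_name)
            if present:
                groups.append(ChargedGroup(+1, present, key, resname))
        if resname in ("POPC", "POPE", "PC", "PE") and "N" in by_name:
            groups.append(ChargedGroup(+1, (by_name["N"],), key, resname))
        if resname in ("POPC", "POPE", "PC", "PE"):
            phos = tuple(by_name[m] for m in ("O13", "O14") if m in by_name)
            if phos:
                groups.append(ChargedGroup(-1, phos, key, resname))

        # optional termini
        if include_termini and protein:
            order = chain_res.get(key.chain, [])
            if order and ridx == order[0] and "N" in by_name:
                groups.append(ChargedGroup(+1, (by_name["N"],), key, resname))
            if order and ridx == order[-1]:
                present = tuple(by_name[m] for m in ("O", "OXT") if m in by_name)
                if present:
                    groups.append(ChargedGroup(-1, present, key, resname))

    return ChemistryAnnotation(
        mode=mode,
        donors=donors,
        acceptors=np.asarray(sorted(set(acceptors)), dtype=int),
        charged_groups=groups,
        is_protein=is_protein,
        is_lipid=is_lipid,
        is_ligand=is_ligand,
        is_water=is_water,
        unknown_residues=unknown,
    )
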