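"""PDB reading/writing and the atom-level data model.

A parsed complex is partitioned into chemical entities: all polymer (ATOM)
chains are merged into one protein structure, and each HETATM residue with
a distinct (chain, residue number, residue name) identity becomes its own
ligand structure.  Waters and common crystallization additives are dropped
through a configurable exclusion list.  Parsing is delegated to gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "ResidueId",
    "DEFAULT_EXCLUDE",
    "StructureFormatError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
]

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)

#: HETATM residue names treated as solvent / crystallization additives
DEFAULT_EXCLUDE = frozenset({"HOH", "DOD", "NA", "CL", "SO4", "GOL", "PEG", "EDO"})

_HEAVY_EXCLUDED = {"H", "D"}


class StructureFormatError(ValueError):
    """File could not be parsed as PDB, or the requested model is absent."""


class EmptyStructureError(ValueError):
    """A structure with no atoms where at least one is required."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: ResidueId
    coordinates: np.ndarray
    is_ca: bool
    is_heavy: bool

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element symbol is empty")
        if self.is_ca and self.name != "CA":
            raise ValueError(f"atom {self.serial}: is_ca set but name is {self.name!r}")


@dataclass
class MolecularStructure:
    """Ordered atom list with a role (protein or ligand) and source model index."""

    atoms: list[AtomRecord]
    role: str = "protein"
    model_index: int = 0
    label: str = ""

    def __post_init__(self):
        if self.role not in ("protein", "ligand"):
            raise ValueError(f"role must be 'protein' or 'ligand', got {self.role!r}")
        if not self.atoms:
            raise EmptyStructureError("structure must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms])

    def ca_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_ca]

    def residue_ids(self) -> list[ResidueId]:
        """Unique residue ids in first-appearance order."""
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def atoms_by_residue(self) -> dict[ResidueId, list[AtomRecord]]:
        groups: dict[ResidueId, list[AtomRecord]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_id, []).append(a)
        return groups

    def residue_names(self) -> dict[ResidueId, str]:
        return {a.residue_id: a.residue_name for a in self.atoms}

    def with_coordinates(self, coords: np.ndarray) -> "MolecularStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.residue_id,
                       c, a.is_ca, a.is_heavy)
            for a, c in zip(self.atoms, coords)
        ]
        return MolecularStructure(atoms, self.role, self.model_index, self.label)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by altloc letter order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def _atom_record(serial: int, res: gemmi.Residue, chain_id: str, atom: gemmi.Atom) -> AtomRecord:
    element = atom.element.name.strip() or atom.name[:1]
    name = atom.name.strip()
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=res.name.strip(),
        residue_id=(chain_id, res.seqid.num, res.seqid.icode.strip()),
        coordinates=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        is_ca=(name == "CA" and element.upper() != "CA"),  # exclude calcium ions
        is_heavy=element.upper() not in _HEAVY_EXCLUDED,
    )


def read_structure(
    path,
    model: int = 0,
    exclude=DEFAULT_EXCLUDE,
) -> list[MolecularStructure]:
    """Read a PDB file and partition it into one protein plus per-residue ligands.

    Parameters
    ----------
    path : str or Path
        PDB file with ATOM/HETATM records; multi-model files are indexed by
        ``model`` (0-based).
    model : int
        Which MODEL block to read (default the first).
    exclude : collection of str
        HETATM residue names to drop (waters, cryo additives).

    Returns
    -------
    list of MolecularStructure
        The merged polymer chains first (role ``protein``), then one
        structure per remaining HETATM residue (role ``ligand``), ordered
        by appearance.  Entities are disjoint and exhaustive over
        non-excluded atoms.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path} as PDB: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models found")
    if model < 0 or model >= len(st):
        raise StructureFormatError(
            f"{path}: model index {model} out of range (file has {len(st)} models)"
        )
    gmodel = st[model]
    exclude = {e.upper() for e in exclude}

    protein_atoms: list[AtomRecord] = []
    ligands: dict[tuple[str, int, str, str], list[AtomRecord]] = {}
    serial = 0
    for chain in gmodel:
        for res in chain:
            resname = res.name.strip().upper()
            is_het = res.het_flag == "H"
            if is_het and resname in exclude:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name in by_name:
                atom = _pick_altloc(by_name[name])
                serial += 1
                rec = _atom_record(serial, res, chain.name, atom)
                if is_het:
                    key = (chain.name, res.seqid.num, res.seqid.icode.strip(), res.name.strip())
                    ligands.setdefault(key, []).append(rec)
                else:
                    protein_atoms.append(rec)

    out: list[MolecularStructure] = []
    if protein_atoms:
        out.append(MolecularStructure(protein_atoms, role="protein",
                                      model_index=model, label="protein"))
    for (chain_id, num, icode, resname), atoms in ligands.items():
        out.append(MolecularStructure(atoms, role="ligand", model_index=model,
                                      label=f"{chain_id}:{num}{icode}:{resname}"))
    if not out:
        raise EmptyStructureError(f"{path}: model {model} contains no usable atoms")
    return out


def write_structure(structure: MolecularStructure, path) -> None:
    """Write a structure as PDB ATOM/HETATM records.

    Round-trips through :func:`read_structure` preserving atom count, names,
    residue identities and coordinates at PDB precision (3 decimals).
    Serial numbers above 99999 wrap modulo 100000, the classic PDB dialect.
    """
    record = "ATOM  " if structure.role == "protein" else "HETATM"
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        serial = i % 100000
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        chain = (a.residue_id[0] or "A")[:1]
        icode = (a.residue_id[2] or " ")[:1]
        x, y, z = a.coordinates
        lines.append(
            f"{record}{serial:>5d} {name:<4s} {a.residue_name:<3s} {chain}"
            f"{a.residue_id[1]:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
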