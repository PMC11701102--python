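"""Minimal atomic-structure I/O and a selection model.

The container is deliberately flat: a :class:`StructureModel` is an ordered
list of :class:`AtomRecord`, in file order, holding author residue numbering
and coordinates in Angstrom.  Parsing of PDB and mmCIF goes through gemmi;
only the first model of multi-model files is kept and alternate locations
are collapsed to a single conformer (altloc blank or "A").

Writing emits fixed-column PDB ATOM/HETATM records, which is the format the
rest of the package (and the synthetic generators) round-trip through.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Selection",
    "EmptyStructureError",
    "FormatError",
    "read_structure",
    "select_atoms",
    "write_structure",
]

#: residue names treated as water throughout
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class EmptyStructureError(ValueError):
    """A parsed file contained no atoms."""


class FormatError(ValueError):
    """The requested or detected structure format is not supported."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, position (A), occupancy and B-factor.

    ``residue_number`` is author numbering; ``insertion_code`` is a single
    character or the empty string.  ``hetero`` marks HETATM records so that
    downstream geometric defaults can skip ligands and waters.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    insertion_code: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    hetero: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Uniqueness key within one model."""
        return (self.chain_id, self.residue_number, self.insertion_code, self.atom_name)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class StructureModel:
    """An ordered collection of atoms with provenance.

    Iteration order is file order and is deterministic.  The tuple
    (chain_id, residue_number, insertion_code, atom_name) is unique.
    """

    identifier: str
    atoms: list[AtomRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom {k} in model {self.identifier!r}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def chain_ids(self) -> list[str]:
        """Chain identifiers in first-appearance order."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_atoms(self, atoms: Iterable[AtomRecord]) -> "StructureModel":
        return StructureModel(self.identifier, list(atoms), self.provenance)


@dataclass(frozen=True)
class Selection:
    """Atom selection: empty criteria match everything.

    ``residue_range`` is inclusive on both ends in author numbering.
    """

    chain_ids: frozenset[str] = frozenset()
    residue_range: tuple[int, int] | None = None
    atom_names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.residue_range is not None:
            start, end = self.residue_range
            if start > end:
                raise ValueError(f"residue range start {start} > end {end}")

    @classmethod
    def of(
        cls,
        chains: Sequence[str] | str | None = None,
        residues: tuple[int, int] | int | None = None,
        atoms: Sequence[str] | str | None = None,
    ) -> "Selection":
        """Convenience constructor: ``Selection.of("A", (91, 308), "CA")``."""
        if isinstance(chains, str):
            chains = [chains]
        if isinstance(atoms, str):
            atoms = [atoms]
        if isinstance(residues, int):
            residues = (residues, residues)
        return cls(
            chain_ids=frozenset(chains or ()),
            residue_range=residues,
            atom_names=frozenset(atoms or ()),
        )

    def matches(self, atom: AtomRecord) -> bool:
        if self.chain_ids and atom.chain_id not in self.chain_ids:
            return False
        if self.residue_range is not None:
            start, end = self.residue_range
            if not start <= atom.residue_number <= end:
                return False
        if self.atom_names and atom.atom_name not in self.atom_names:
            return False
        return True


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gz":
        suffix = Path(path.stem).suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise FormatError(f"cannot infer structure format from {path.name!r}; pass format=")


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is returned.  For alternate
    locations, conformer "A" (or blank) is kept and the rest dropped, so the
    result is a deterministic single-conformer structure.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"structure file not found: {p}")
    if format == "auto":
        format = _detect_format(p)
    if format == "pdb":
        coor = gemmi.CoorFormat.Pdb
    elif format == "mmcif":
        coor = gemmi.CoorFormat.Mmcif
    else:
        raise FormatError(f"unknown structure format {format!r}")
    try:
        st = gemmi.read_structure(str(p), format=coor)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"failed to parse {p}: {exc}") from exc

    atoms: list[AtomRecord] = []
    if len(st) > 0:
        model = st[0]  # MODEL 1 only
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H"
                for atom in residue:
                    if atom.altloc not in ("", "\0", "A"):
                        continue
                    atoms.append(
                        AtomRecord(
                            chain_id=chain.name,
                            residue_number=residue.seqid.num,
                            insertion_code=(residue.seqid.icode or "").strip(),
                            residue_name=residue.name,
                            atom_name=atom.name,
                            element=atom.element.name,
                            position=(atom.pos.x, atom.pos.y, atom.pos.z),
                            occupancy=min(max(atom.occ, 0.0), 1.0),
                            b_factor=atom.b_iso,
                            hetero=het,
                        )
                    )
    if not atoms:
        raise EmptyStructureError(f"no atoms in {p}")
    return StructureModel(
        identifier=st.name or p.stem,
        atoms=atoms,
        provenance=f"{p} ({format})",
    )


def select_atoms(model: StructureModel, sel: Selection) -> list[AtomRecord]:
    """Atoms of ``model`` matching every non-empty criterion, in model order.

    An empty result is valid; selection is idempotent.
    """
    return [a for a in model.atoms if sel.matches(a)]


def _pdb_atom_line(serial: int, a: AtomRecord) -> str:
    record = "HETATM" if a.hetero else "ATOM  "
    name = a.atom_name
    # PDB convention: 1-letter elements start in column 14
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.position
    return (
        f"{record}{serial:>5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
        f"{a.chain_id[:1]:1s}{a.residue_number:>4d}{a.insertion_code[:1] or '':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element.upper():>2s}"
    )


def write_structure(model: StructureModel, path: str | os.PathLike, format: str = "pdb") -> None:
    """Write fixed-column PDB ATOM records; B-factors with 2 decimals."""
    if format != "pdb":
        raise FormatError(f"unsupported output format {format!r}")
    if len(model) == 0:
        raise EmptyStructureError("refusing to write an empty model")
    p = Path(path)
    lines = []
    serial = 0
    prev_chain: str | None = None
    for a in model.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            serial += 1
            lines.append(f"TER   {serial:>5d}")
        serial += 1
        lines.append(_pdb_atom_line(serial, a))
        prev_chain = a.chain_id
    lines.append("END")
    try:
        p.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write structure to {p}: {exc}") from exc
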