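"""Reading PDB-format structures and centered radial geometry.

The similarity metric needs only four things per atom: element, coordinates,
residue identity and chain.  Structures are parsed with :mod:`gemmi` and
flattened into an immutable list of :class:`AtomRecord`, because every
downstream operation works on the atom cloud, not on the PDB hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "StructureParseError",
    "read_structure",
    "geometric_center",
    "radial_distances",
]

#: Names gemmi flags as water; excluded by default together with HETATM.
_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed or yields no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One accepted coordinate record.

    Coordinates are kept in the file's native length unit; the layer
    boundaries of the similarity metric are interpreted in the same unit.
    """

    element: str
    coords: tuple[float, float, float]
    residue_name: str
    residue_id: int
    chain: str

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates {self.coords}")


@dataclass(frozen=True)
class ProteinStructure:
    """An identified, ordered collection of atoms."""

    id: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError(f"structure {self.id!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in file order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


def _from_atoms(struct_id: str, atoms: Iterable[AtomRecord]) -> ProteinStructure:
    return ProteinStructure(id=struct_id, atoms=tuple(atoms))


def read_structure(
    path: str | Path,
    include_hetatm: bool = False,
    include_waters: bool = False,
    include_hydrogens: bool = True,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Defaults accept ATOM records only (waters and other HETATM groups
    excluded, hydrogens kept when present).  Only the first model and the
    first alternate location of each atom are used.

    Parameters
    ----------
    path
        PDB-format file.
    include_hetatm
        Accept HETATM records (waters still require ``include_waters``).
    include_waters
        Accept water residues (HOH/WAT/DOD); implies they also pass the
        HETATM filter.
    include_hydrogens
        Keep hydrogen/deuterium atoms.

    Raises
    ------
    StructureParseError
        On unreadable input or when no atom passes the filters.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")

    atoms: list[AtomRecord] = []
    model = st[0]  # first model only
    for chain in model:
        for residue in chain:
            is_water = residue.name.strip().upper() in _WATER_NAMES or residue.is_water()
            is_het = residue.het_flag == "H"
            if is_water and not include_waters:
                continue
            if is_het and not is_water and not include_hetatm:
                continue
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue  # first altloc only
                element = atom.element.name.strip()
                if not element or element == "X":
                    # fall back to the leading letters of the atom name
                    element = "".join(c for c in atom.name if c.isalpha())[:2].capitalize()
                if element in ("H", "D") and not include_hydrogens:
                    continue
                atoms.append(
                    AtomRecord(
                        element=element,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        residue_name=residue.name.strip(),
                        residue_id=residue.seqid.num,
                        chain=chain.name,
                    )
                )
    if not atoms:
        raise StructureParseError(f"{path}: zero atoms accepted under current filters")
    return _from_atoms(path.stem, atoms)


def geometric_center(s: ProteinStructure) -> np.ndarray:
    """Unweighted arithmetic mean of the atom coordinates (3-vector)."""
    return s.coords.mean(axis=0)


def radial_distances(s: ProteinStructure) -> np.ndarray:
    """Euclidean distance of every atom from the geometric center.

    Order-preserving: entry *i* belongs to atom *i*.  Centering on the
    geometric center makes the result translation-invariant.
    """
    centered = s.coords - geometric_center(s)
    return np.linalg.norm(centered, axis=1)


# --- PDB writing ----------------------------------------------------------

def write_pdb(s: ProteinStructure, path: str | Path) -> Path:
    """Write a structure as fixed-column PDB ATOM records.

    Coordinates are rounded to the format's 0.001 precision; the element
    symbol goes both into the atom-name field and columns 77-78, so the file
    survives a round trip through :func:`read_structure`.
    """
    path = Path(path)
    lines = []
    for i, a in enumerate(s.atoms, start=1):
        name = a.element.upper()[:2]
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i % 100000:5d} {name:>3s}  {a.residue_name:<3s} {a.chain[:1]}"
            f"{a.residue_id % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00          {a.element.upper()[:2]:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def structure_from_arrays(
    struct_id: str,
    coords: np.ndarray | Sequence[Sequence[float]],
    elements: Sequence[str],
    residue_ids: Sequence[int] | None = None,
    residue_names: Sequence[str] | None = None,
    chain: str = "A",
) -> ProteinStructure:
    """Assemble a structure from parallel arrays (used by generators/tests)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if residue_ids is None:
        residue_ids = [1] * n
    if residue_names is None:
        residue_names = ["GLY"] * n
    atoms = [
        AtomRecord(
            element=elements[i],
            coords=(float(coords[i, 0]), float(coords[i, 1]), float(coords[i, 2])),
            residue_name=residue_names[i],
            residue_id=int(residue_ids[i]),
            chain=chain,
        )
        for i in range(n)
    ]
    return _from_atoms(struct_id, atoms)
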