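"""Read PDB/mmCIF files into a validated heavy-atom structure model.

Structures are reduced to the parts the surface analysis needs: standard
amino-acid residues, heavy atoms only (hydrogens dropped; AlphaFold models
are heavy-atom anyway), one altloc per atom (highest occupancy), no waters
or other heteroatoms, and the first model of multi-model files. Van der
Waals radii are assigned at load time from a configurable table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DEFAULT_RADII",
    "STANDARD_RESIDUES",
    "StructureError",
    "RadiiTableError",
    "EmptyStructureError",
    "read_structure",
    "residue_sequence",
    "write_pdb",
]

#: Heavy-atom van der Waals radii (Å), Bondi-style values for the elements
#: occurring in the 20 standard amino acids. Configurable per call.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,  # selenomethionine, if mapped in via nonstandard_map
    "H": 1.20,   # present only if drop_hydrogens=False
}

STANDARD_RESIDUES: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Base error for structure parsing/validation failures."""


class RadiiTableError(StructureError):
    """An atom's element has no entry in the radii table."""


class EmptyStructureError(StructureError):
    """No standard amino-acid residues survived filtering."""


@dataclass
class Atom:
    """One heavy atom: label, element, coordinates (Å), vdW radius (Å) and
    the B-factor column value (pLDDT confidence in AlphaFold files)."""

    name: str
    element: str
    coords: np.ndarray
    radius: float
    confidence: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.radius > 0:
            raise StructureError(f"atom {self.name}: radius must be positive")


@dataclass
class Residue:
    """A standard amino-acid residue: 0-based chain position, three-letter
    code and its heavy atoms (backbone N, CA, C required)."""

    index: int
    three_letter: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def validate(self) -> None:
        if self.three_letter not in STANDARD_RESIDUES:
            raise StructureError(f"nonstandard residue {self.three_letter!r}")
        for req in ("N", "CA", "C"):
            if self.atom(req) is None:
                raise StructureError(
                    f"residue {self.three_letter} {self.index}: missing backbone atom {req}"
                )


@dataclass
class Structure:
    """Heavy-atom model: ordered chains of ordered residues."""

    protein_id: str
    chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyStructureError(f"{self.protein_id}: no chains")
        for cid, residues in self.chains.items():
            if not residues:
                raise EmptyStructureError(f"{self.protein_id}: chain {cid} empty")
            for i, r in enumerate(residues):
                if r.index != i:
                    raise StructureError(
                        f"{self.protein_id}: chain {cid} residue indices not consecutive"
                    )

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        for cid, residues in self.chains.items():
            for r in residues:
                yield cid, r

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def all_atoms(self) -> list[Atom]:
        return [a for _, r in self.iter_residues() for a in r.atoms]

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.all_atoms()])

    def atom_radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.all_atoms()])


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(
    path: str | Path,
    format: str = "auto",
    radii: dict[str, float] | None = None,
    nonstandard_map: dict[str, str] | None = None,
    drop_hydrogens: bool = True,
    min_confidence: float | None = None,
) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Waters and heteroatoms are excluded, altlocs resolved to highest
    occupancy, hydrogens dropped, and only the first model of multi-model
    files is read. Nonstandard residues are rejected unless mapped to a
    standard code via ``nonstandard_map`` (e.g. ``{"MSE": "MET"}``).
    ``min_confidence`` optionally drops residues whose mean B-factor/pLDDT
    is below the threshold (off by default: no confidence filtering).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    radii = dict(DEFAULT_RADII if radii is None else radii)
    nonstandard_map = nonstandard_map or {}

    try:
        if fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except StructureError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError on bad input
        raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest-occupancy altloc
    st.remove_ligands_and_waters()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no models")
    model = st[0]  # first model only (NMR multi-model)

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            name = res.name.upper()
            if name in nonstandard_map:
                name = nonstandard_map[name].upper()
            if name == "HOH":
                continue
            if name not in STANDARD_RESIDUES:
                raise StructureError(
                    f"{path}: nonstandard residue {res.name!r} in chain {chain.name} "
                    "(use nonstandard_map to map it, or remove it)"
                )
            atoms: list[Atom] = []
            for at in res:
                elem = at.element.name.upper()
                if drop_hydrogens and elem in ("H", "D"):
                    continue
                if elem not in radii:
                    raise RadiiTableError(
                        f"{path}: element {elem!r} (atom {at.name}) has no radius in the table"
                    )
                atoms.append(
                    Atom(
                        name=at.name,
                        element=elem,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        radius=radii[elem],
                        confidence=float(at.b_iso),
                    )
                )
            if not atoms:
                continue
            r = Residue(index=len(residues), three_letter=name, atoms=atoms)
            r.validate()
            if min_confidence is not None:
                mean_conf = float(np.mean([a.confidence for a in r.atoms]))
                if mean_conf < min_confidence:
                    continue
            residues.append(r)
        # re-index after any confidence drops so indices stay consecutive
        for i, r in enumerate(residues):
            r.index = i
        if residues:
            chains[chain.name] = residues

    if not chains:
        raise EmptyStructureError(f"{path}: no standard amino-acid residues after filtering")
    return Structure(protein_id=path.stem, chains=chains)


def residue_sequence(s: Structure) -> list[tuple[str, int, str]]:
    """Ordered ``(chain, index, three_letter)`` triples, file order."""
    return [(cid, r.index, r.three_letter) for cid, r in s.iter_residues()]


def write_pdb(s: Structure, path: str | Path) -> None:
    """Serialize a Structure as minimal PDB ATOM records (fixture support)."""
    lines: list[str] = []
    serial = 1
    for cid, residues in s.chains.items():
        for r in residues:
            for a in r.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{r.three_letter:>4s} {cid:1s}"
                    f"{r.index + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}"
                    f"{a.confidence:6.2f}          {a.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mmcif(s: Structure, path: str | Path) -> None:
    """Serialize a Structure as a minimal mmCIF atom_site loop."""
    rows = []
    serial = 1
    for cid, residues in s.chains.items():
        for r in residues:
            for a in r.atoms:
                x, y, z = a.coords
                rows.append(
                    f"ATOM {serial} {a.element} {a.name} . {r.three_letter} {cid} "
                    f"{r.index + 1} ? {x:.3f} {y:.3f} {z:.3f} 1.00 {a.confidence:.2f}"
                )
                serial += 1
    header = (
        f"data_{s.protein_id}\n"
        "loop_\n"
        "_atom_site.group_PDB\n"
        "_atom_site.id\n"
        "_atom_site.type_symbol\n"
        "_atom_site.label_atom_id\n"
        "_atom_site.label_alt_id\n"
        "_atom_site.label_comp_id\n"
        "_atom_site.label_asym_id\n"
        "_atom_site.label_seq_id\n"
        "_atom_site.pdbx_PDB_ins_code\n"
        "_atom_site.Cartn_x\n"
        "_atom_site.Cartn_y\n"
        "_atom_site.Cartn_z\n"
        "_atom_site.occupancy\n"
        "_atom_site.B_iso_or_equiv\n"
    )
    Path(path).write_text(header + "\n".join(rows) + "\n")
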