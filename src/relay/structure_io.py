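"""Macromolecular structure I/O, atom selection and crystallographic symmetry.

Structures are held as flat lists of :class:`AtomRecord` plus crystallographic
metadata (unit cell, space-group symbol, symmetry operators).  Author residue
numbering is the canonical coordinate system throughout; hydrogens and waters
are excluded from counts and geometry by default.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "Selection",
    "StructureSummary",
    "read_structure",
    "write_structure",
    "select_atoms",
    "expand_symmetry",
    "summarize_structure",
    "BUNDLED_SPACEGROUP_OPS",
]

#: Three-letter codes treated as polymer (protein) residues.
PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE SEC PYL CSO SEP TPO PTR""".split()
)

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

MAINCHAIN_CB_ATOMS = frozenset({"N", "CA", "C", "O", "CB"})
MAINCHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Symmetry operators (rotation, fractional translation) for space groups that
# files in the wild sometimes record without REMARK 290 / _symmetry_equiv
# loops.  Operators for anything else are read from the file itself.
_I = np.eye(3)
_2Y = np.diag([-1.0, 1.0, -1.0])  # 2-fold along b
BUNDLED_SPACEGROUP_OPS: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
    "P 1": [(_I, np.zeros(3))],
    "P 1 2 1": [(_I, np.zeros(3)), (_2Y, np.zeros(3))],
    "P 2": [(_I, np.zeros(3)), (_2Y, np.zeros(3))],
    "I 1 2 1": [
        (_I, np.zeros(3)),
        (_2Y, np.zeros(3)),
        (_I, np.array([0.5, 0.5, 0.5])),
        (_2Y, np.array([0.5, 0.5, 0.5])),
    ],
    "C 1 2 1": [
        (_I, np.zeros(3)),
        (_2Y, np.zeros(3)),
        (_I, np.array([0.5, 0.5, 0.0])),
        (_2Y, np.array([0.5, 0.5, 0.0])),
    ],
    "P 21 21 21": [
        (_I, np.zeros(3)),
        (np.diag([-1.0, -1.0, 1.0]), np.array([0.5, 0.0, 0.5])),
        (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.5])),
        (np.diag([1.0, -1.0, -1.0]), np.array([0.5, 0.5, 0.0])),
    ],
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class StructureFormatError(ValueError):
    """Raised for an unknown or unsupported coordinate format."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom site, heavy on identity so selections stay unambiguous."""

    chain: str
    resseq: int
    icode: str
    resname: str
    atom: str
    element: str
    xyz: tuple[float, float, float]
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    hetero: bool = False

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_protein(self) -> bool:
        return self.resname in PROTEIN_RESNAMES

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.xyz):
            raise ValueError(f"non-finite coordinates for atom {self.atom}")


@dataclass
class Structure:
    """Atom list plus crystallographic metadata."""

    atoms: list[AtomRecord]
    cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    id: str = ""

    def __post_init__(self):
        if self.cell is not None and any(v <= 0 for v in self.cell[:3]):
            raise ValueError(f"invalid cell lengths in {self.cell}")
        seen = set()
        for a in self.atoms:
            key = (a.chain, a.resseq, a.icode, a.atom, a.altloc)
            if key in seen:
                raise ValueError(f"duplicate atom identity {key}")
            seen.add(key)

    def coords(self, atoms: Sequence[AtomRecord] | None = None) -> np.ndarray:
        src = self.atoms if atoms is None else atoms
        return np.asarray([a.xyz for a in src], dtype=float).reshape(-1, 3)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def chain_sequence(self, chain: str) -> tuple[str, list[tuple[str, int, str]]]:
        """One-letter sequence of a chain's protein residues (CA-bearing), with ids."""
        seq, ids = [], []
        for a in self.atoms:
            if a.chain != chain or a.atom != "CA" or not a.is_protein:
                continue
            if a.residue_id in ids:
                continue  # altloc duplicate CA
            seq.append(THREE_TO_ONE.get(a.resname, "X"))
            ids.append(a.residue_id)
        return "".join(seq), ids

    def fractionalization_matrix(self) -> np.ndarray:
        """Matrix turning orthogonal (Å) coordinates into fractional ones."""
        if self.cell is None:
            raise ValueError("structure has no unit cell")
        return np.linalg.inv(_orthogonalization_matrix(self.cell))


@dataclass
class Selection:
    """Declarative atom filter; ``atom_class`` names a standard atom subset."""

    chains: set[str] | None = None
    residue_ranges: list[tuple[int, int]] | None = None
    atom_class: str = "all-heavy"
    exclude_water: bool = True
    exclude_hydrogen: bool = True
    altloc_policy: str = "highest-occupancy"

    _CLASSES = ("all-heavy", "CA", "mainchain+CB", "sidechain")

    def __post_init__(self):
        if self.atom_class not in self._CLASSES:
            raise ValueError(
                f"atom_class {self.atom_class!r} not one of {self._CLASSES}"
            )
        if self.altloc_policy not in ("first", "highest-occupancy"):
            raise ValueError(f"unknown altloc_policy {self.altloc_policy!r}")
        if self.residue_ranges is not None:
            for lo, hi in self.residue_ranges:
                if lo > hi:
                    raise ValueError(f"ill-ordered residue range ({lo}, {hi})")


@dataclass
class StructureSummary:
    n_protein_atoms: int
    n_water: int
    mean_b_protein: float | None
    mean_b_water: float | None
    cell: tuple[float, float, float, float, float, float] | None
    spacegroup: str | None = None


# ---------------------------------------------------------------------------
# reading / writing


def read_structure(path: str | Path, format: str = "auto", model: int = 1) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM sites are kept (including every altloc conformer); cell
    and symmetry operators are captured when the file provides them.  Author
    numbering is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            fmt = "pdb"
        elif suffix in (".cif", ".mmcif"):
            fmt = "mmcif"
        else:
            raise StructureFormatError(f"cannot infer format from {path.name!r}")
    if fmt == "pdb":
        return _read_pdb(path, model)
    if fmt == "mmcif":
        return _read_mmcif(path, model)
    raise StructureFormatError(f"unknown format {fmt!r}")


def _read_pdb(path: Path, model: int) -> Structure:
    import biotite.structure.io.pdb as pdbio

    try:
        pf = pdbio.PDBFile.read(str(path))
        arr = pdbio.get_structure(
            pf, model=model, altloc="all", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    cell, spacegroup = _parse_cryst1(path)
    sym_ops = _parse_remark290(path)
    if not sym_ops and spacegroup:
        sym_ops = list(BUNDLED_SPACEGROUP_OPS.get(spacegroup, []))
    atoms = _atoms_from_biotite(arr)
    return Structure(
        atoms=atoms, cell=cell, spacegroup=spacegroup, symmetry_ops=sym_ops,
        id=path.stem,
    )


def _read_mmcif(path: Path, model: int) -> Structure:
    import biotite.structure.io.pdbx as pdbx

    try:
        cf = pdbx.CIFFile.read(str(path))
        arr = pdbx.get_structure(
            cf, model=model, altloc="all", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:  # pragma: no cover
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    block = next(iter(cf.values()))
    cell = None
    spacegroup = None
    try:
        c = block["cell"]
        cell = tuple(
            float(c[k].as_item())
            for k in ("length_a", "length_b", "length_c",
                      "angle_alpha", "angle_beta", "angle_gamma")
        )
    except KeyError:
        pass
    try:
        spacegroup = str(block["symmetry"]["space_group_name_H-M"].as_item())
    except KeyError:
        pass
    sym_ops = []
    if spacegroup:
        sym_ops = list(BUNDLED_SPACEGROUP_OPS.get(spacegroup, []))
    atoms = _atoms_from_biotite(arr)
    return Structure(
        atoms=atoms, cell=cell, spacegroup=spacegroup, symmetry_ops=sym_ops,
        id=path.stem,
    )


def _atoms_from_biotite(arr) -> list[AtomRecord]:
    atoms = []
    n = arr.array_length()
    bf = arr.get_annotation("b_factor") if "b_factor" in arr.get_annotation_categories() else np.zeros(n)
    occ = arr.get_annotation("occupancy") if "occupancy" in arr.get_annotation_categories() else np.ones(n)
    for i in range(n):
        icode = str(arr.ins_code[i]).strip()
        atoms.append(
            AtomRecord(
                chain=str(arr.chain_id[i]),
                resseq=int(arr.res_id[i]),
                icode=icode,
                resname=str(arr.res_name[i]),
                atom=str(arr.atom_name[i]),
                element=str(arr.element[i]).upper(),
                xyz=tuple(float(v) for v in arr.coord[i]),
                bfactor=float(bf[i]),
                occupancy=float(occ[i]),
                altloc=str(arr.altloc_id[i]).strip().replace(".", "")
                if "altloc_id" in arr.get_annotation_categories() else "",
                hetero=bool(arr.hetero[i]),
            )
        )
    return atoms


def _parse_cryst1(path: Path):
    cell = None
    spacegroup = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    cell = (
                        float(line[6:15]), float(line[15:24]), float(line[24:33]),
                        float(line[33:40]), float(line[40:47]), float(line[47:54]),
                    )
                except ValueError as exc:
                    raise StructureParseError(f"bad CRYST1 record: {line!r}") from exc
                spacegroup = line[55:66].strip()
                break
    # a 1 Å placeholder cell means "no crystal information"
    if cell is not None and cell[:3] == (1.0, 1.0, 1.0):
        return None, None
    return cell, spacegroup


def _parse_remark290(path: Path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Collect SMTRY operator rows from REMARK 290."""
    rows: dict[int, list[tuple[np.ndarray, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("REMARK 290   SMTRY"):
                continue
            parts = line.split()
            # REMARK 290 SMTRY<i> <n> r11 r12 r13 t
            axis = int(parts[2][5:])
            op_no = int(parts[3])
            vals = [float(v) for v in parts[4:8]]
            rows.setdefault(op_no, [None, None, None])[axis - 1] = (
                np.array(vals[:3]), vals[3]
            )
    ops = []
    for op_no in sorted(rows):
        triple = rows[op_no]
        if any(r is None for r in triple):
            continue
        rot = np.vstack([r[0] for r in triple])
        trans = np.array([r[1] for r in triple])
        ops.append((rot, trans))
    return ops


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a structure as PDB (coordinates to 3 decimals, B to 2)."""
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdbio

    n = len(s.atoms)
    arr = bst.AtomArray(n)
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("occupancy", dtype=float)
    for i, a in enumerate(s.atoms):
        arr.chain_id[i] = a.chain
        arr.res_id[i] = a.resseq
        arr.ins_code[i] = a.icode
        arr.res_name[i] = a.resname
        arr.atom_name[i] = a.atom
        arr.element[i] = a.element
        arr.coord[i] = a.xyz
        arr.b_factor[i] = a.bfactor
        arr.occupancy[i] = a.occupancy
        arr.hetero[i] = a.hetero
    pf = pdbio.PDBFile()
    pdbio.set_structure(pf, arr)
    lines = pf.lines
    if s.cell is not None:
        a, b, c, al, be, ga = s.cell
        sg = (s.spacegroup or "P 1")[:11]
        cryst = (
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
            f"{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}   1"
        )
        lines = [cryst] + lines
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selection


def _resolve_altlocs(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    """Collapse altloc groups to one conformer per (residue, atom name)."""
    groups: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.resseq, a.icode, a.atom)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    out = []
    for key in order:
        grp = groups[key]
        if len(grp) == 1:
            out.append(grp[0])
        elif policy == "first":
            out.append(grp[0])
        else:  # highest occupancy; ties broken by altloc label
            out.append(max(grp, key=lambda a: (a.occupancy, -ord(a.altloc or "Z"))))
    return out


def select_atoms(s: Structure, sel: Selection) -> list[AtomRecord]:
    """Atoms satisfying every clause of ``sel``, in (chain, resseq, icode, atom) order."""
    atoms = []
    for a in s.atoms:
        if sel.exclude_water and a.is_water:
            continue
        if sel.exclude_hydrogen and a.is_hydrogen:
            continue
        if sel.chains is not None and a.chain not in sel.chains:
            continue
        if sel.residue_ranges is not None:
            if not any(lo <= a.resseq <= hi for lo, hi in sel.residue_ranges):
                continue
        if sel.atom_class == "CA":
            if a.atom != "CA" or not a.is_protein:
                continue
        elif sel.atom_class == "mainchain+CB":
            if a.atom not in MAINCHAIN_CB_ATOMS or not a.is_protein:
                continue
        elif sel.atom_class == "sidechain":
            if a.atom in MAINCHAIN_ATOMS or not a.is_protein:
                continue
        atoms.append(a)
    atoms = _resolve_altlocs(atoms, sel.altloc_policy)
    if sel.residue_ranges is not None and not atoms:
        logger.warning("selection with ranges %s matched no atoms", sel.residue_ranges)
    atoms.sort(key=lambda a: (a.chain, a.resseq, a.icode, a.atom))
    return atoms


# ---------------------------------------------------------------------------
# symmetry


def _orthogonalization_matrix(cell) -> np.ndarray:
    a, b, c, alpha, beta, gamma = cell
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    sg = math.sin(math.radians(gamma))
    v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
    return np.array([
        [a, b * cg, c * cb],
        [0.0, b * sg, c * (ca - cb * cg) / sg],
        [0.0, 0.0, c * v / sg],
    ])


def expand_symmetry(
    s: Structure, radius: float, max_shell: int = 2
) -> list[tuple[str, Structure]]:
    """Symmetry/lattice copies with at least one atom within ``radius`` of ``s``.

    The identity copy (identity operator, zero lattice shift) is excluded.
    Labels are ``"op<k>+(i,j,l)"`` with k indexing the file's operator list.
    """
    if s.cell is None or not s.symmetry_ops:
        raise ValueError("structure lacks cell or symmetry operators")
    if radius <= 0:
        return []
    ortho = _orthogonalization_matrix(s.cell)
    frac_inv = np.linalg.inv(ortho)
    xyz = s.coords()
    frac = xyz @ frac_inv.T
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    mates = []
    shifts = range(-max_shell, max_shell + 1)
    for k, (rot, trans) in enumerate(s.symmetry_ops):
        base = frac @ rot.T + trans
        for i in shifts:
            for j in shifts:
                for l in shifts:
                    shift = np.array([i, j, l], dtype=float)
                    is_identity = np.allclose(rot, np.eye(3)) and np.allclose(
                        trans + shift, 0.0
                    )
                    if is_identity:
                        continue
                    cart = (base + shift) @ ortho.T
                    d, _ = tree.query(cart, k=1, distance_upper_bound=radius)
                    if not np.any(np.isfinite(d)):
                        continue
                    if np.min(d) > radius:
                        continue
                    new_atoms = [
                        replace(a, xyz=tuple(cart[m])) for m, a in enumerate(s.atoms)
                    ]
                    label = f"op{k}+({i},{j},{l})"
                    mates.append((label, Structure(
                        atoms=new_atoms, cell=s.cell, spacegroup=s.spacegroup,
                        symmetry_ops=[], id=f"{s.id}|{label}",
                    )))
    return mates


# ---------------------------------------------------------------------------
# summary


def summarize_structure(s: Structure) -> StructureSummary:
    """Heavy-atom counts and mean B-factors, waters and polymer separated.

    Altloc conformers are counted once per deposited atom site (i.e. both
    conformers of a two-state side chain contribute), matching how deposited
    atom counts are tallied.
    """
    prot = [a for a in s.atoms if a.is_protein and not a.is_hydrogen and not a.is_water]
    wat = [a for a in s.atoms if a.is_water and not a.is_hydrogen]
    mean_b_p = round(float(np.mean([a.bfactor for a in prot])), 1) if prot else None
    mean_b_w = round(float(np.mean([a.bfactor for a in wat])), 1) if wat else None
    return StructureSummary(
        n_protein_atoms=len(prot),
        n_water=len(wat),
        mean_b_protein=mean_b_p,
        mean_b_water=mean_b_w,
        cell=s.cell,
        spacegroup=s.spacegroup,
    )
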