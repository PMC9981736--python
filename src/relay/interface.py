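"""Interface analysis: residue contacts, SASA, buried areas, crystal contacts,
salt bridges.

SASA uses a Shrake–Rupley sphere-point sampler (golden-spiral points, probe
1.4 Å, 960 points/atom by default).  Interface area follows the two-side
average convention area = (SASA_A + SASA_B - SASA_AB) / 2; the report also
carries both per-side buried areas so either reading can be used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, Selection, Structure, expand_symmetry, select_atoms

__all__ = [
    "ContactSet",
    "InterfaceReport",
    "SaltBridge",
    "residue_contacts",
    "shrake_rupley_sasa",
    "interface_area",
    "crystal_contact_scan",
    "detect_salt_bridges",
    "VDW_RADII",
]

#: van der Waals radii (Å) used for SASA; unknown elements fall back to DEFAULT.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "D": 1.20, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98, "MG": 1.73, "ZN": 1.39, "FE": 1.40,
    "NA": 2.27, "K": 2.75, "CA": 2.31, "MN": 1.39, "BE": 1.53,
}
DEFAULT_RADIUS = 1.70

ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}


@dataclass
class ContactSet:
    """Residue pairs with minimum cross-group heavy-atom distance <= loose."""

    contacts: list[tuple[tuple, tuple, float]]
    loose: float = 8.0
    tight: float = 6.0
    patch_labels: dict | None = None

    def tight_contacts(self) -> list[tuple[tuple, tuple, float]]:
        return [c for c in self.contacts if c[2] <= self.tight]

    def __contains__(self, pair) -> bool:
        return any((a, b) == pair for a, b, _ in self.contacts)


@dataclass
class InterfaceReport:
    area: float
    partner: str
    buried_a: float
    buried_b: float
    per_residue_burial: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SaltBridge:
    acidic: tuple  # (chain, resseq, resname)
    basic: tuple
    distance: float


def residue_contacts(
    group_a: Sequence[AtomRecord],
    group_b: Sequence[AtomRecord],
    loose: float = 8.0,
    tight: float = 6.0,
) -> ContactSet:
    """Minimum heavy-atom distance per cross-group residue pair, thresholded."""
    if loose < tight:
        raise ValueError(f"loose ({loose}) must be >= tight ({tight})")
    group_a = [a for a in group_a if not a.is_hydrogen]
    group_b = [b for b in group_b if not b.is_hydrogen]
    if not group_a or not group_b:
        raise ValueError("contact groups must be non-empty")
    xa = np.array([a.xyz for a in group_a])
    xb = np.array([b.xyz for b in group_b])
    tree = cKDTree(xb)
    best: dict[tuple, float] = {}
    for i, hits in enumerate(tree.query_ball_point(xa, loose)):
        ra = group_a[i].residue_id
        for j in hits:
            rb = group_b[j].residue_id
            d = float(np.linalg.norm(xa[i] - xb[j]))
            key = (ra, rb)
            if key not in best or d < best[key]:
                best[key] = d
    contacts = sorted(
        [(ra, rb, d) for (ra, rb), d in best.items()],
        key=lambda c: (c[0], c[1]),
    )
    return ContactSet(contacts=contacts, loose=loose, tight=tight)


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )


def shrake_rupley_sasa(
    atoms: Sequence[AtomRecord] | Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by sphere-point sampling."""
    if isinstance(atoms, Structure):
        atoms = select_atoms(atoms, Selection())
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for acceptable sampling error")
    radii = radii or VDW_RADII
    n = len(atoms)
    if n == 0:
        return np.zeros(0)
    xyz = np.array([a.xyz for a in atoms])
    r = np.array([radii.get(a.element, DEFAULT_RADIUS) for a in atoms]) + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(xyz)
    max_r = r.max()
    areas = np.zeros(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(xyz[i], r[i] + max_r) if j != i]
        surf = xyz[i] + r[i] * pts
        if neigh:
            nx = xyz[neigh]
            nr = r[np.asarray(neigh)]
            d2 = ((surf[:, None, :] - nx[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (nr ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r[i] ** 2
    return areas


def interface_area(
    group_a: Sequence[AtomRecord],
    group_b: Sequence[AtomRecord],
    probe: float = 1.4,
    n_points: int = 960,
    partner: str = "",
) -> InterfaceReport:
    """Buried surface between two atom groups, two-side average convention."""
    # disjointness by object identity: symmetry mates legitimately reuse
    # residue/atom names, but one atom object may not sit in both groups
    if {id(a) for a in group_a} & {id(b) for b in group_b}:
        raise ValueError("interface groups must be disjoint")
    group_a = list(group_a)
    group_b = list(group_b)
    sasa_a = shrake_rupley_sasa(group_a, probe, n_points)
    sasa_b = shrake_rupley_sasa(group_b, probe, n_points)
    sasa_ab = shrake_rupley_sasa(group_a + group_b, probe, n_points)
    buried_a = float(sasa_a.sum() - sasa_ab[: len(group_a)].sum())
    buried_b = float(sasa_b.sum() - sasa_ab[len(group_a):].sum())
    area = 0.5 * (buried_a + buried_b)
    per_res: dict = {}
    lost = np.concatenate([sasa_a, sasa_b]) - sasa_ab
    for atom, delta in zip(group_a + group_b, lost):
        per_res[atom.residue_id] = per_res.get(atom.residue_id, 0.0) + float(delta)
    return InterfaceReport(
        area=area, partner=partner, buried_a=buried_a, buried_b=buried_b,
        per_residue_burial=per_res,
    )


def crystal_contact_scan(
    s: Structure,
    radius: float = 5.0,
    probe: float = 1.4,
    n_points: int = 240,
) -> list[InterfaceReport]:
    """Interface area against every symmetry mate within ``radius``, sorted
    by area descending."""
    base = select_atoms(s, Selection())
    reports = []
    for label, mate in expand_symmetry(s, radius):
        mate_atoms = select_atoms(mate, Selection())
        rep = interface_area(base, mate_atoms, probe, n_points, partner=label)
        reports.append(rep)
    reports.sort(key=lambda r: -r.area)
    return reports


def detect_salt_bridges(
    s: Structure,
    cutoff: float = 4.0,
    scope: str = "both",
) -> list[SaltBridge]:
    """Asp/Glu side-chain O to Arg/Lys side-chain N pairs within ``cutoff``.

    One record per residue pair, carrying the minimum O–N distance.
    """
    if scope not in ("intra-chain", "inter-chain", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    atoms = select_atoms(s, Selection())
    acid = [a for a in atoms if a.resname in ACIDIC and a.atom in ACIDIC[a.resname]]
    base = [a for a in atoms if a.resname in BASIC and a.atom in BASIC[a.resname]]
    best: dict[tuple, float] = {}
    for a in acid:
        for b in base:
            if scope == "intra-chain" and a.chain != b.chain:
                continue
            if scope == "inter-chain" and a.chain == b.chain:
                continue
            d = float(np.linalg.norm(np.subtract(a.xyz, b.xyz)))
            if d > cutoff:
                continue
            key = ((a.chain, a.resseq, a.resname), (b.chain, b.resseq, b.resname))
            if key not in best or d < best[key]:
                best[key] = d
    return sorted(
        (SaltBridge(acidic=k[0], basic=k[1], distance=v) for k, v in best.items()),
        key=lambda sb: (sb.acidic, sb.basic),
    )
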