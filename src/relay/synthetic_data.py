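"""Seeded fixture generators with known ground truth for every pipeline stage.

Each generator draws from its own pseudo-random stream derived from
``(seed, generator name)``, so adding a generator never shifts the output of
an existing one, and identical configuration reproduces identical fixtures.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .interface import residue_contacts
from .msa_profiles import AA_INDEX, AA_ORDER, Alignment
from .nmr_shifts import RandomCoilTable, ResidueShifts, ShiftTable, load_random_coil_table
from .structure_io import AtomRecord, Selection, Structure, select_atoms
from .superpose import RigidTransform

__all__ = [
    "rng_for",
    "make_helix_domain",
    "make_graft_scenario",
    "simulate_msa",
    "simulate_shift_pair",
    "random_rigid_transform",
]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Deterministic stream keyed by (seed, generator name)."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def random_rigid_transform(rng: np.random.Generator, max_shift: float = 20.0) -> RigidTransform:
    """Uniform random rotation (QR of a Gaussian matrix) + uniform translation."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(Q, t)


# ---------------------------------------------------------------------------
# structures

_HELIX_RISE = 1.5       # Å per residue along the axis
_HELIX_TWIST = 100.0    # degrees per residue
_HELIX_RADIUS = 2.3     # Å, CA distance from the axis


def make_helix_domain(
    n_res: int,
    rise: float = _HELIX_RISE,
    twist: float = _HELIX_TWIST,
    sidechain: str = "CB-stub",
    chain: str = "A",
    start_res: int = 1,
    resname: str = "ALA",
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Structure:
    """Ideal α-helical main chain (N, CA, C, O, optional CB stub) along +z."""
    if n_res < 4:
        raise ValueError("need at least 4 residues for a helix")
    if sidechain not in ("CB-stub", "none"):
        raise ValueError(f"unknown sidechain mode {sidechain!r}")
    ca = np.zeros((n_res, 3))
    for i in range(n_res):
        ang = math.radians(twist * i)
        ca[i] = (_HELIX_RADIUS * math.cos(ang), _HELIX_RADIUS * math.sin(ang), rise * i)
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        ca = ca + rng.normal(scale=noise, size=ca.shape)
    atoms: list[AtomRecord] = []
    use_cb = sidechain == "CB-stub" and resname != "GLY"
    for i in range(n_res):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        next_ca = ca[i + 1] if i < n_res - 1 else ca[i] + (ca[i] - ca[i - 1])
        n_pos = 0.65 * ca[i] + 0.35 * prev_ca
        c_pos = 0.65 * ca[i] + 0.35 * next_ca
        radial = np.array([ca[i][0], ca[i][1], 0.0])
        nr = np.linalg.norm(radial)
        radial = radial / nr if nr > 1e-9 else np.array([1.0, 0.0, 0.0])
        o_pos = c_pos + 1.23 * radial
        resseq = start_res + i
        for name, pos, elem in (
            ("N", n_pos, "N"), ("CA", ca[i], "C"), ("C", c_pos, "C"), ("O", o_pos, "O"),
        ):
            atoms.append(AtomRecord(
                chain=chain, resseq=resseq, icode="", resname=resname,
                atom=name, element=elem, xyz=tuple(pos),
            ))
        if use_cb:
            cb = ca[i] + 1.53 * radial
            atoms.append(AtomRecord(
                chain=chain, resseq=resseq, icode="", resname=resname,
                atom="CB", element="C", xyz=tuple(cb),
            ))
    return Structure(atoms=atoms, id=f"helix_{chain}")


@dataclass
class GraftScenario:
    template: Structure
    donors: list[Structure]
    scramble_transforms: list[RigidTransform]
    anchor_ranges: list[tuple[list[tuple[int, int]], list[tuple[int, int]]]]
    template_chains: list[str]
    expected_contacts: list


def make_graft_scenario(
    seed: int = 0,
    n_res: int = 16,
    separation: float = 9.0,
    noise: float = 0.0,
    scramble: str = "random",
) -> GraftScenario:
    """Template = two helical domains in contact; donors = scrambled copies.

    Returns the ground-truth scramble transforms (grafting should recover
    their inverses), per-component anchor ranges and the template's
    inter-domain contact list.
    """
    rng = rng_for(seed, "graft")
    dom1 = make_helix_domain(n_res, chain="A", start_res=101)
    dom2_raw = make_helix_domain(n_res, chain="B", start_res=201)
    # put domain 2 alongside domain 1, axes parallel, touching distance
    from .superpose import apply_transform

    shift = RigidTransform(np.eye(3), np.array([separation, 0.0, 0.0]))
    dom2 = apply_transform(dom2_raw, shift)
    template = Structure(atoms=dom1.atoms + dom2.atoms, id="template")

    transforms = []
    donors = []
    for dom, name in ((dom1, "scramble1"), (dom2, "scramble2")):
        if scramble == "identity":
            tr = RigidTransform.identity()
        else:
            tr = random_rigid_transform(rng_for(seed, name))
        moved = apply_transform(dom, tr)
        if noise > 0:
            nrng = rng_for(seed, name + "_noise")
            xyz = moved.coords() + nrng.normal(scale=noise, size=(len(moved.atoms), 3))
            from dataclasses import replace

            moved = Structure(
                atoms=[replace(a, xyz=tuple(xyz[i])) for i, a in enumerate(moved.atoms)],
                id=moved.id,
            )
        donors.append(moved)
        transforms.append(tr)
    anchor_ranges = [
        ([(101, 100 + n_res)], [(101, 100 + n_res)]),
        ([(201, 200 + n_res)], [(201, 200 + n_res)]),
    ]
    contacts = residue_contacts(
        select_atoms(template, Selection(chains={"A"})),
        select_atoms(template, Selection(chains={"B"})),
        loose=8.0, tight=6.0,
    ).contacts
    return GraftScenario(
        template=template, donors=donors, scramble_transforms=transforms,
        anchor_ranges=anchor_ranges, template_chains=["A", "B"],
        expected_contacts=contacts,
    )


# ---------------------------------------------------------------------------
# alignments


@dataclass
class MsaTruth:
    coupled_pairs: list[tuple[int, int]]
    joint_distributions: dict[tuple[int, int], dict[tuple[str, str], float]]
    motif_start: int | None
    motif_pattern: str | None
    conserved_columns: dict[int, str]


def simulate_msa(
    n_seqs: int = 500,
    n_cols: int = 60,
    seed: int = 0,
    conservation: float = 0.55,
    column_profiles: dict[int, dict[str, float]] | None = None,
    coupled_pairs: list[tuple[int, int, dict[tuple[str, str], float]]] | None = None,
    motif: tuple[int, str, float] | None = None,
    reference_start: int = 1,
) -> tuple[Alignment, MsaTruth]:
    """Sample an ungapped alignment with planted structure.

    Background columns each get a random preferred residue at frequency
    ``conservation`` with the rest spread uniformly; ``column_profiles`` maps
    selected columns to explicit residue distributions instead.
    ``coupled_pairs`` plants
    jointly sampled column pairs, e.g. charge-reversal mixtures like
    ``{("R","E"): 0.5, ("E","R"): 0.5}``.  ``motif`` = (start column 0-based,
    pattern of specific residues, per-position fidelity) forces a motif.
    """
    rng = rng_for(seed, "msa")
    coupled_pairs = coupled_pairs or []
    for i, j, dist in coupled_pairs:
        tot = sum(dist.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError(f"joint distribution for ({i},{j}) sums to {tot}")
    coupled_cols = {c for i, j, _ in coupled_pairs for c in (i, j)}

    column_profiles = column_profiles or {}
    for col, dist in column_profiles.items():
        tot = sum(dist.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError(f"column profile for {col} sums to {tot}")

    prefs = {}
    rows = np.empty((n_seqs, n_cols), dtype=np.int8)
    for col in range(n_cols):
        if col in column_profiles:
            dist = column_profiles[col]
            p = np.zeros(20)
            for aa, prob in dist.items():
                p[AA_INDEX[aa]] = prob
            prefs[col] = max(dist, key=dist.get)
        else:
            pref = int(rng.integers(0, 20))
            prefs[col] = AA_ORDER[pref]
            p = np.full(20, (1.0 - conservation) / 19.0)
            p[pref] = conservation
        rows[:, col] = rng.choice(20, size=n_seqs, p=p)

    for i, j, dist in coupled_pairs:
        combos = list(dist)
        probs = np.array([dist[c] for c in combos])
        draw = rng.choice(len(combos), size=n_seqs, p=probs)
        for s in range(n_seqs):
            ri, rj = combos[draw[s]]
            rows[s, i] = AA_INDEX[ri]
            rows[s, j] = AA_INDEX[rj]

    motif_start = motif_pattern = None
    if motif is not None:
        start, pattern, fidelity = motif
        motif_start, motif_pattern = start, pattern
        for k, ch in enumerate(pattern):
            if ch in ("x", "X"):
                continue
            col = start + k
            hit = rng.random(n_seqs) < fidelity
            rows[hit, col] = AA_INDEX[ch]
            prefs[col] = ch

    seqs = ["".join(AA_ORDER[c] for c in row) for row in rows]
    ids = [f"seq{i:04d}" for i in range(n_seqs)]
    aln = Alignment(
        ids=ids, seqs=seqs, reference_row=ids[0], reference_start=reference_start
    )
    truth = MsaTruth(
        coupled_pairs=[(i, j) for i, j, _ in coupled_pairs],
        joint_distributions={(i, j): d for i, j, d in coupled_pairs},
        motif_start=motif_start,
        motif_pattern=motif_pattern,
        conserved_columns={c: p for c, p in prefs.items() if c not in coupled_cols},
    )
    return aln, truth


# ---------------------------------------------------------------------------
# shift tables


@dataclass
class ShiftTruth:
    helical_segments: list[tuple[int, int]]
    perturbed: dict[int, float]


def simulate_shift_pair(
    n_res: int = 80,
    seed: int = 0,
    helical_segments: list[tuple[int, int]] | None = None,
    helix_offset_ca: float = 2.8,
    helix_offset_cb: float = -0.4,
    perturbation: dict[int, float] | None = None,
    noise: float = 0.02,
    start_res: int = 1,
    rc: RandomCoilTable | None = None,
) -> tuple[ShiftTable, ShiftTable, ShiftTruth]:
    """Reference/modified shift-table pair with planted helices and CSP cluster.

    The reference table is random coil plus helical Cα/Cβ offsets on the given
    segments plus Gaussian noise; the modified table additionally moves the
    amide shifts of the ``perturbation`` residues so their combined CSP equals
    the requested magnitude (split between the ¹H and scaled ¹⁵N terms).
    """
    rng = rng_for(seed, "shifts")
    rc = rc or load_random_coil_table()
    helical_segments = helical_segments or []
    perturbation = perturbation or {}
    types = rng.choice([aa for aa in AA_ORDER if aa not in "GP"], size=n_res)

    def in_helix(num):
        return any(lo <= num <= hi for lo, hi in helical_segments)

    ref: dict[int, ResidueShifts] = {}
    mod: dict[int, ResidueShifts] = {}
    for k in range(n_res):
        num = start_res + k
        rt = str(types[k])
        ca = rc.ca[rt] + (helix_offset_ca if in_helix(num) else 0.0)
        cb = rc.cb[rt] + (helix_offset_cb if in_helix(num) else 0.0)
        ca += rng.normal(scale=noise)
        cb += rng.normal(scale=noise)
        h = 8.2 + rng.normal(scale=0.3)
        n15 = 118.0 + rng.normal(scale=3.0)
        ref[num] = ResidueShifts(restype=rt, h=h, n=n15, ca=ca, cb=cb)
        dd = perturbation.get(num, 0.0)
        # split the requested perturbation 60/80 between 1H and scaled 15N
        dh = 0.6 * dd
        dn = 0.8 * dd * 5.0
        mod[num] = ResidueShifts(
            restype=rt,
            h=h + dh + rng.normal(scale=noise),
            n=n15 + dn + rng.normal(scale=noise * 5.0),
            ca=ca + rng.normal(scale=noise),
            cb=cb + rng.normal(scale=noise),
        )
    truth = ShiftTruth(
        helical_segments=list(helical_segments), perturbed=dict(perturbation)
    )
    return ShiftTable(shifts=ref), ShiftTable(shifts=mod), truth
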