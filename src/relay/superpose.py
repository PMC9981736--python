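"""Rigid-body superposition: Kabsch fits, residue pairing, iterative pruning."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .structure_io import AtomRecord, Selection, Structure, select_atoms

__all__ = [
    "RigidTransform",
    "ResiduePairing",
    "SuperpositionResult",
    "kabsch_fit",
    "match_residues",
    "iterative_superpose",
    "apply_transform",
]


class GeometryError(ValueError):
    """Degenerate input geometry (too few or collinear points)."""


class ConvergenceError(RuntimeError):
    """Iterative pruning removed too many pairs to continue."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation has det != +1 (improper)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class ResiduePairing:
    """Ordered residue correspondences between two structures."""

    pairs: list[tuple[tuple, tuple]]
    source: str = "user-supplied ranges"

    def __post_init__(self):
        seen_a, seen_b = set(), set()
        for a, b in self.pairs:
            if a in seen_a or b in seen_b:
                raise ValueError(f"residue appears in more than one pair: {a} / {b}")
            seen_a.add(a)
            seen_b.add(b)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_retained: int
    retained_pairs: ResiduePairing | None = None
    n_iterations: int = 1


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(moving: np.ndarray, fixed: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` (Kabsch/SVD).

    Both inputs are (n, 3) arrays with matched rows; no pruning is done.
    """
    P = np.asarray(moving, dtype=float).reshape(-1, 3)
    Q = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise GeometryError(f"point counts differ: {P.shape[0]} vs {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the line unconstrained
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise GeometryError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    tr = RigidTransform(R, t)
    return SuperpositionResult(
        transform=tr, rmsd=_rmsd(tr.apply(P), Q), n_retained=n, n_iterations=1
    )


def match_residues(
    a: Structure,
    b: Structure,
    sel_a: Selection | None = None,
    sel_b: Selection | None = None,
    mode: str = "sequence",
    ranges_a: list[tuple[int, int]] | None = None,
    ranges_b: list[tuple[int, int]] | None = None,
    open_gap: float = -10.0,
    extend_gap: float = -0.5,
    matrix: str = "BLOSUM62",
) -> ResiduePairing:
    """Pair residues of two structures either by sequence or by ranges.

    ``sequence`` mode globally aligns the one-letter sequences of the selected
    chains (end gaps free) and pairs aligned non-gap columns.  ``ranges`` mode
    zips user-supplied residue ranges positionally and requires equal lengths.
    """
    sel_a = sel_a or Selection(atom_class="CA")
    sel_b = sel_b or Selection(atom_class="CA")
    atoms_a = select_atoms(a, sel_a)
    atoms_b = select_atoms(b, sel_b)
    if not atoms_a or not atoms_b:
        raise ValueError("empty selection on one of the structures")

    if mode == "ranges":
        if ranges_a is None or ranges_b is None:
            # fall back to the selections' own ranges as the pairing spec
            ranges_a = sel_a.residue_ranges
            ranges_b = sel_b.residue_ranges
        ids_a = [x.residue_id for x in _ca_in_ranges(atoms_a, ranges_a)]
        ids_b = [x.residue_id for x in _ca_in_ranges(atoms_b, ranges_b)]
        if len(ids_a) != len(ids_b):
            raise ValueError(
                f"ranges resolve to unequal residue counts: {len(ids_a)} vs {len(ids_b)}"
            )
        return ResiduePairing(list(zip(ids_a, ids_b)), source="user-supplied ranges")

    if mode != "sequence":
        raise ValueError(f"unknown pairing mode {mode!r}")

    from Bio import Align
    from Bio.Align import substitution_matrices

    seq_a, ids_a = _sequence_of(atoms_a)
    seq_b, ids_b = _sequence_of(atoms_b)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.end_gap_score = 0.0
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        for off in range(ea - sa):
            pairs.append((ids_a[sa + off], ids_b[sb + off]))
    return ResiduePairing(pairs, source="sequence-alignment")


def _ca_in_ranges(atoms: Sequence[AtomRecord], ranges):
    out = []
    if ranges is None:
        return [a for a in atoms if a.atom == "CA"]
    for lo, hi in ranges:
        out.extend(
            a for a in atoms if a.atom == "CA" and lo <= a.resseq <= hi
        )
    return out


def _sequence_of(atoms: Sequence[AtomRecord]):
    from .structure_io import THREE_TO_ONE

    seq, ids = [], []
    for a in atoms:
        if a.atom != "CA":
            continue
        seq.append(THREE_TO_ONE.get(a.resname, "X"))
        ids.append(a.residue_id)
    return "".join(seq), ids


DEFAULT_PRUNE = {"cutoff_factor": 2.0, "abs_cutoff": 3.5, "max_iter": 10}


def iterative_superpose(
    a: Structure,
    b: Structure,
    pairing: ResiduePairing,
    prune: dict | None = None,
) -> SuperpositionResult:
    """Superpose CA atoms of ``a`` onto ``b`` over ``pairing`` with outlier pruning.

    Each round fits the retained pairs, then drops pairs whose post-fit
    distance exceeds ``max(cutoff_factor * rmsd, abs_cutoff)``; stops when the
    retained set is stable or after ``max_iter`` rounds.
    """
    cfg = dict(DEFAULT_PRUNE)
    if prune:
        cfg.update(prune)
    ca_a = _ca_lookup(a)
    ca_b = _ca_lookup(b)
    pairs = [(pa, pb) for pa, pb in pairing.pairs if pa in ca_a and pb in ca_b]
    if len(pairs) < 3:
        raise GeometryError(f"only {len(pairs)} usable pairs")
    retained = list(pairs)
    result = None
    for it in range(1, int(cfg["max_iter"]) + 1):
        P = np.array([ca_a[pa] for pa, _ in retained])
        Q = np.array([ca_b[pb] for _, pb in retained])
        fit = kabsch_fit(P, Q)
        d = np.linalg.norm(fit.transform.apply(P) - Q, axis=1)
        cut = max(cfg["cutoff_factor"] * fit.rmsd, cfg["abs_cutoff"])
        keep = d <= cut
        result = SuperpositionResult(
            transform=fit.transform,
            rmsd=fit.rmsd,
            n_retained=len(retained),
            retained_pairs=ResiduePairing(list(retained), source=pairing.source),
            n_iterations=it,
        )
        if np.all(keep):
            return result
        new_retained = [p for p, k in zip(retained, keep) if k]
        if len(new_retained) < 3:
            raise ConvergenceError(
                f"pruning left {len(new_retained)} pairs at iteration {it}"
            )
        retained = new_retained
    return result


def _ca_lookup(s: Structure) -> dict:
    sel = Selection(atom_class="CA")
    return {a.residue_id: np.asarray(a.xyz) for a in select_atoms(s, sel)}


def apply_transform(s: Structure, t: RigidTransform) -> Structure:
    """Return a copy of ``s`` with every coordinate mapped x -> R x + t."""
    moved = t.apply(s.coords())
    atoms = [replace(a, xyz=tuple(moved[i])) for i, a in enumerate(s.atoms)]
    return Structure(
        atoms=atoms, cell=s.cell, spacegroup=s.spacegroup,
        symmetry_ops=list(s.symmetry_ops), id=s.id,
    )
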