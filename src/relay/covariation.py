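"""Pairwise column couplings (mutual information with average-product
correction, z-standardized), pair substitution tables, charge-reversal
statistics, and coupling-vs-distance agreement.

The scorer is MI-APC; externally computed coupling tables (two residue
columns + score) can be imported so the distance-agreement analysis can also
run on scores from heavier inference engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa_profiles import AA_INDEX, AA_ORDER, Alignment

__all__ = [
    "CovariationResult",
    "PairSubstitutionTable",
    "AgreementReport",
    "covariation_scores",
    "pair_substitution_table",
    "charge_reversal_fraction",
    "covariation_vs_distance",
    "read_coupling_table",
]

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")


@dataclass
class CovariationResult:
    mi: np.ndarray            # raw MI (bits), symmetric, nan outside retained set
    apc: np.ndarray           # APC-corrected MI
    z: np.ndarray             # standardized APC scores
    columns: np.ndarray       # retained column indices
    column_numbers: list      # reference residue number per alignment column
    threshold: float = 3.0

    def pairs_above(self, threshold: float | None = None):
        """(col_i, col_j, z) for retained pairs with z above the threshold."""
        thr = self.threshold if threshold is None else threshold
        out = []
        cols = list(self.columns)
        for ii, i in enumerate(cols):
            for j in cols[ii + 1:]:
                zv = self.z[i, j]
                if np.isfinite(zv) and zv > thr:
                    out.append((i, j, float(zv)))
        out.sort(key=lambda t: -t[2])
        return out


def _weighted_joint(
    enc: np.ndarray, i: int, j: int, weights: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, float]:
    """Pairwise-complete weighted joint counts for columns i, j (+pseudocount)."""
    ci, cj = enc[:, i], enc[:, j]
    mask = (ci >= 0) & (cj >= 0)
    joint = np.zeros((20, 20))
    np.add.at(joint, (ci[mask], cj[mask]), weights[mask])
    n_eff = float(weights[mask].sum())
    joint += pseudocount / 400.0
    return joint, n_eff


def _mi_from_joint(joint: np.ndarray) -> float:
    p = joint / joint.sum()
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log2(p) - np.log2(pi) - np.log2(pj))
    return float(np.nansum(terms))


def covariation_scores(
    a: Alignment,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.5,
    max_gap_fraction: float = 0.5,
    min_effective_n: float = 20.0,
    threshold: float = 3.0,
) -> CovariationResult:
    """MI-APC coupling scores over all retained column pairs.

    Columns with gap fraction above ``max_gap_fraction`` are dropped.  The APC
    correction is MIc(i,j) = MI(i,j) - mean_i(MI) * mean_j(MI) / mean(MI); the
    corrected scores are z-standardized over the retained off-diagonal pairs.
    """
    enc = a.encoded()
    n, w = enc.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    n_eff_total = float(weights.sum())
    if n_eff_total < min_effective_n:
        raise ValueError(
            f"effective sequence count {n_eff_total:.1f} below floor "
            f"{min_effective_n}; add sequences or lower the floor"
        )
    gapf = (enc < 0).mean(axis=0)
    cols = np.where(gapf <= max_gap_fraction)[0]
    if len(cols) < 2:
        raise ValueError("fewer than 2 columns survive the gap filter")
    mi = np.full((w, w), np.nan)
    for ii, i in enumerate(cols):
        mi[i, i] = 0.0
        for j in cols[ii + 1:]:
            joint, _ = _weighted_joint(enc, i, j, weights, pseudocount)
            v = _mi_from_joint(joint)
            mi[i, j] = mi[j, i] = v
    sub = mi[np.ix_(cols, cols)]
    k = len(cols)
    off = ~np.eye(k, dtype=bool)
    col_mean = np.array([sub[r, off[r]].mean() for r in range(k)])
    overall = sub[off].mean()
    apc_sub = sub - np.outer(col_mean, col_mean) / overall
    apc = np.full((w, w), np.nan)
    apc[np.ix_(cols, cols)] = apc_sub
    vals = apc_sub[np.triu_indices(k, 1)]
    mu, sd = vals.mean(), vals.std(ddof=0)
    z = np.full((w, w), np.nan)
    z[np.ix_(cols, cols)] = (apc_sub - mu) / sd if sd > 0 else 0.0
    np.fill_diagonal(z, np.nan)
    return CovariationResult(
        mi=mi, apc=apc, z=z, columns=cols,
        column_numbers=a.column_numbers(), threshold=threshold,
    )


@dataclass
class PairSubstitutionTable:
    joint: np.ndarray  # (20, 20) weighted counts, row = column i, col = column j
    column_i: int
    column_j: int
    n_effective: float

    @property
    def marginal_i(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def marginal_j(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    def cell(self, res_i: str, res_j: str) -> float:
        return float(self.joint[AA_INDEX[res_i], AA_INDEX[res_j]])


def pair_substitution_table(
    a: Alignment,
    i: int,
    j: int,
    weights: np.ndarray | None = None,
) -> PairSubstitutionTable:
    """Weighted joint residue counts for one column pair (gaps dropped pairwise)."""
    enc = a.encoded()
    if not (0 <= i < a.width and 0 <= j < a.width):
        raise IndexError(f"columns ({i}, {j}) outside alignment width {a.width}")
    if weights is None:
        weights = np.ones(enc.shape[0])
    joint, n_eff = _weighted_joint(enc, i, j, np.asarray(weights, float), 0.0)
    return PairSubstitutionTable(joint=joint, column_i=i, column_j=j, n_effective=n_eff)


def charge_reversal_fraction(
    t: PairSubstitutionTable, histidine_positive: bool = False
) -> dict:
    """Fractions of (+,-), (-,+) and other residue-class combinations.

    ``balance`` is min/max of the two oppositely-charged fractions (1.0 when a
    salt bridge appears equally often in both orientations).
    """
    if t.n_effective <= 0:
        return {"f_plus_minus": np.nan, "f_minus_plus": np.nan,
                "f_other": np.nan, "balance": np.nan, "empty": True}
    pos = set(POSITIVE_RESIDUES) | ({"H"} if histidine_positive else set())
    pos_idx = [AA_INDEX[r] for r in pos]
    neg_idx = [AA_INDEX[r] for r in NEGATIVE_RESIDUES]
    total = t.joint.sum()
    f_pm = float(t.joint[np.ix_(pos_idx, neg_idx)].sum() / total)
    f_mp = float(t.joint[np.ix_(neg_idx, pos_idx)].sum() / total)
    f_other = 1.0 - f_pm - f_mp
    hi = max(f_pm, f_mp)
    balance = float(min(f_pm, f_mp) / hi) if hi > 0 else np.nan
    return {"f_plus_minus": f_pm, "f_minus_plus": f_mp,
            "f_other": f_other, "balance": balance, "empty": False}


@dataclass
class AgreementReport:
    entries: list  # dicts: residue_i, residue_j, score, distance, klass
    precision_tight: float | None
    precision_loose: float | None
    tight: float
    loose: float
    unmapped: list = field(default_factory=list)

    def ion_pair_candidates(self, tables: dict | None = None) -> list:
        return [e for e in self.entries if e.get("ion_pair")]


def covariation_vs_distance(
    c: CovariationResult,
    distances: dict[tuple[int, int], float],
    score_threshold: float | None = None,
    tight: float = 6.0,
    loose: float = 8.0,
    region: tuple[list[tuple[int, int]], list[tuple[int, int]]] | None = None,
) -> AgreementReport:
    """Join scored pairs above threshold with model distances and grade them.

    ``distances`` maps (residue_number_i, residue_number_j) -> minimum
    heavy-atom distance (Å); keys are looked up in both orders.  ``region``
    optionally restricts pairs to (ranges for side i, ranges for side j).
    Precision at a distance class = fraction of mapped scored pairs within it.
    """
    thr = c.threshold if score_threshold is None else score_threshold
    entries, unmapped = [], []
    for i, j, zv in c.pairs_above(thr):
        ri = c.column_numbers[i]
        rj = c.column_numbers[j]
        if ri is None or rj is None:
            unmapped.append({"column_i": int(i), "column_j": int(j), "score": zv})
            continue
        if region is not None:
            side_i, side_j = region
            in_i = any(lo <= ri <= hi for lo, hi in side_i)
            in_j = any(lo <= rj <= hi for lo, hi in side_j)
            in_i_swap = any(lo <= rj <= hi for lo, hi in side_i)
            in_j_swap = any(lo <= ri <= hi for lo, hi in side_j)
            if in_i and in_j:
                pass
            elif in_i_swap and in_j_swap:
                ri, rj = rj, ri
            else:
                continue
        d = distances.get((ri, rj), distances.get((rj, ri)))
        if d is None:
            unmapped.append({"residue_i": ri, "residue_j": rj, "score": zv})
            continue
        if d < tight:
            klass = "red"
        elif d < loose:
            klass = "black"
        else:
            klass = "miss"
        entries.append({
            "residue_i": ri, "residue_j": rj, "score": zv,
            "distance": float(d), "class": klass,
        })
    n = len(entries)
    prec_t = sum(e["class"] == "red" for e in entries) / n if n else None
    prec_l = sum(e["class"] in ("red", "black") for e in entries) / n if n else None
    return AgreementReport(
        entries=entries, precision_tight=prec_t, precision_loose=prec_l,
        tight=tight, loose=loose, unmapped=unmapped,
    )


def read_coupling_table(path: str | Path) -> list[tuple[int, int, float]]:
    """Import an externally computed coupling table: ``res_i res_j score`` rows."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise ValueError(f"line {ln}: expected 'res_i res_j score'")
        out.append((int(parts[0]), int(parts[1]), float(parts[2])))
    return out
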