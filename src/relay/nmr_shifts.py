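"""Backbone chemical-shift analytics.

Implements amide chemical-shift perturbation with the 1/5-scaled nitrogen
term, combined Cα/Cβ secondary shifts against a random-coil reference with
1-2-1 smoothing, heteronuclear-NOE mobility flags and Gaussian line-width
(FWHM) fitting.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ShiftTable",
    "RandomCoilTable",
    "CSPProfile",
    "SecondaryShiftProfile",
    "load_random_coil_table",
    "read_shift_table",
    "csp",
    "secondary_shifts",
    "smooth_121",
    "hetnoe_flags",
    "gaussian_fwhm",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548... per sigma


@dataclass(frozen=True)
class ResidueShifts:
    restype: str
    h: float | None = None
    n: float | None = None
    ca: float | None = None
    cb: float | None = None


@dataclass
class ShiftTable:
    """Per-residue backbone shifts; any nucleus may be unassigned (None)."""

    shifts: dict[int, ResidueShifts]

    def __post_init__(self):
        nums = list(self.shifts)
        if nums != sorted(nums):
            raise ValueError("residue numbers must be strictly increasing")
        for num, rs in self.shifts.items():
            for v in (rs.h, rs.n, rs.ca, rs.cb):
                if v is not None and not math.isfinite(v):
                    raise ValueError(f"non-finite shift at residue {num}")

    @property
    def residues(self) -> list[int]:
        return list(self.shifts)


@dataclass
class RandomCoilTable:
    ca: dict[str, float]
    cb: dict[str, float | None]

    def __post_init__(self):
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.ca)
        if missing:
            raise ValueError(f"random-coil table missing residue types {sorted(missing)}")


def load_random_coil_table() -> RandomCoilTable:
    """The bundled Cα/Cβ random-coil reference."""
    text = resources.files("relay.data").joinpath("random_coil_ca_cb.csv").read_text()
    ca, cb = {}, {}
    for row in csv.DictReader(
        (l for l in text.splitlines() if not l.startswith("#"))
    ):
        ca[row["restype"]] = float(row["ca"])
        cb[row["restype"]] = float(row["cb"]) if row["cb"] else None
    return RandomCoilTable(ca=ca, cb=cb)


def read_shift_table(path: str | Path) -> ShiftTable:
    """Read a shift table in the minimal CSV dialect or NMR-STAR-style rows.

    CSV: header ``resnum,restype,h,n,ca,cb`` (blank cells = unassigned).
    STAR-style: whitespace rows ``<resnum> <restype3or1> <atom> <value>``
    accumulated per residue (atom names H, N, CA, CB).
    """
    path = Path(path)
    text = path.read_text()
    first = next(
        (l for l in text.splitlines() if l.strip() and not l.startswith("#")), ""
    )
    if "," in first:
        return _read_csv_shifts(text)
    return _read_star_shifts(text)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _read_csv_shifts(text: str) -> ShiftTable:
    rows = {}
    for row in csv.DictReader(
        (l for l in text.splitlines() if l.strip() and not l.startswith("#"))
    ):
        num = int(row["resnum"])
        get = lambda k: float(row[k]) if row.get(k, "").strip() else None
        rows[num] = ResidueShifts(
            restype=row["restype"].strip().upper(),
            h=get("h"), n=get("n"), ca=get("ca"), cb=get("cb"),
        )
    return ShiftTable(shifts=dict(sorted(rows.items())))


def _read_star_shifts(text: str) -> ShiftTable:
    acc: dict[int, dict] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "loop_", "_", "stop_")):
            continue
        parts = line.split()
        if len(parts) < 4:
            continue
        num = int(parts[0])
        rt = parts[1].upper()
        rt = _THREE_TO_ONE.get(rt, rt if len(rt) == 1 else "X")
        atom = parts[2].upper()
        val = float(parts[3])
        d = acc.setdefault(num, {"restype": rt})
        if atom in ("H", "HN"):
            d["h"] = val
        elif atom == "N":
            d["n"] = val
        elif atom == "CA":
            d["ca"] = val
        elif atom == "CB":
            d["cb"] = val
    return ShiftTable(shifts={
        num: ResidueShifts(**vals) for num, vals in sorted(acc.items())
    })


# ---------------------------------------------------------------------------
# chemical shift perturbation


@dataclass
class CSPProfile:
    delta: dict[int, float]           # residue -> combined amide perturbation (ppm)
    classes: dict[int, str]           # none | medium | strong
    unassigned: list[int]
    t1: float
    t2: float

    def class_counts(self) -> dict[str, int]:
        out = {"none": 0, "medium": 0, "strong": 0}
        for c in self.classes.values():
            out[c] += 1
        return out


def csp(
    ref: ShiftTable, mod: ShiftTable, t1: float = 0.2, t2: float = 0.4
) -> CSPProfile:
    """Combined amide perturbation per residue.

    ΔΔ(HN) = sqrt((δH_ref - δH)^2 + ((δN_ref - δN)/5)^2); residues lacking an
    amide assignment in either table are reported unassigned.  Classes:
    strong for ΔΔ >= t2, medium for t1 <= ΔΔ < t2, else none.
    """
    delta, classes, unassigned = {}, {}, []
    for num in sorted(set(ref.residues) | set(mod.residues)):
        a = ref.shifts.get(num)
        b = mod.shifts.get(num)
        if a is None or b is None or a.h is None or b.h is None \
                or a.n is None or b.n is None:
            unassigned.append(num)
            continue
        if a.restype != b.restype:
            warnings.warn(
                f"residue {num}: type mismatch {a.restype} vs {b.restype}; "
                "computing anyway"
            )
        dd = math.sqrt((a.h - b.h) ** 2 + ((a.n - b.n) / 5.0) ** 2)
        delta[num] = dd
        classes[num] = "strong" if dd >= t2 else ("medium" if dd >= t1 else "none")
    return CSPProfile(delta=delta, classes=classes, unassigned=unassigned, t1=t1, t2=t2)


# ---------------------------------------------------------------------------
# secondary shifts


def smooth_121(series: dict[int, float]) -> dict[int, float]:
    """1-2-1 smoothing with edge reflection at series ends and gaps.

    Interior points become (x[i-1] + 2 x[i] + x[i+1]) / 4.  Where a neighbor
    is missing (series end or unassigned gap) the centre value stands in for
    it, so an impulse [0, 1, 0] smooths to [0.25, 0.5, 0.25], values are never
    mixed across gaps, and the mean of a gap-free series is preserved exactly.
    Gaps stay gaps (absent keys stay absent).
    """
    out = {}
    for num, val in series.items():
        left = series.get(num - 1, val)
        right = series.get(num + 1, val)
        out[num] = (left + 2.0 * val + right) / 4.0
    return out


@dataclass
class SecondaryShiftProfile:
    raw: dict[int, float]
    smoothed: dict[int, float]
    propensity: dict[int, str]        # helix | strand | coil
    glycine_flagged: list[int]


def secondary_shifts(
    t: ShiftTable,
    rc: RandomCoilTable | None = None,
    helix_threshold: float = 0.7,
    strand_threshold: float = -0.7,
    helix_run: int = 4,
    strand_run: int = 3,
) -> SecondaryShiftProfile:
    """Combined secondary shifts (ΔδCα - ΔδCβ) with smoothing and propensity calls.

    Glycine contributes its Cα term only (no Cβ), and is flagged.  Propensity:
    runs of smoothed values >= helix_threshold spanning >= helix_run residues
    are called helix; runs <= strand_threshold over >= strand_run residues are
    strand; everything else coil.
    """
    rc = rc or load_random_coil_table()
    raw: dict[int, float] = {}
    gly_flagged = []
    for num, rs in t.shifts.items():
        if rs.ca is None:
            continue
        if rs.restype not in rc.ca:
            raise KeyError(f"no random-coil entry for residue type {rs.restype!r}")
        d_ca = rs.ca - rc.ca[rs.restype]
        if rs.restype == "G":
            d_cb = 0.0
            gly_flagged.append(num)
        else:
            if rs.cb is None:
                continue
            rc_cb = rc.cb.get(rs.restype)
            if rc_cb is None:
                raise KeyError(f"no random-coil Cβ for residue type {rs.restype!r}")
            d_cb = rs.cb - rc_cb
        raw[num] = d_ca - d_cb
    smoothed = smooth_121(raw)
    propensity = {num: "coil" for num in smoothed}
    _mark_runs(smoothed, propensity, lambda v: v >= helix_threshold, helix_run, "helix")
    _mark_runs(smoothed, propensity, lambda v: v <= strand_threshold, strand_run, "strand")
    return SecondaryShiftProfile(
        raw=raw, smoothed=smoothed, propensity=propensity,
        glycine_flagged=gly_flagged,
    )


def _mark_runs(series, propensity, pred, min_run, label):
    nums = sorted(series)
    run: list[int] = []
    for num in nums + [None]:
        contiguous = run and num is not None and num == run[-1] + 1
        if num is not None and pred(series[num]) and (not run or contiguous):
            run.append(num)
            continue
        if len(run) >= min_run:
            for r in run:
                propensity[r] = label
        run = [num] if (num is not None and pred(series[num])) else []
    # trailing run handled by the None sentinel above


# ---------------------------------------------------------------------------
# dynamics and line widths


def hetnoe_flags(
    values: dict[int, float], threshold: float = 0.65
) -> dict[int, bool]:
    """Flag residues as mobile when the heteronuclear NOE ratio < threshold."""
    flags = {}
    for num, v in values.items():
        if not -1.5 < v < 1.2:
            warnings.warn(f"residue {num}: HetNOE {v:.2f} outside plausible range")
        flags[num] = v < threshold
    return flags


def gaussian_fwhm(
    x: np.ndarray, y: np.ndarray, baseline: bool = False
) -> dict:
    """Least-squares Gaussian fit of a 1-D trace; FWHM = 2 sqrt(2 ln 2) sigma."""
    from scipy.optimize import curve_fit

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 points spanning the peak")

    def model(xx, amp, mu, sigma, off=0.0):
        return amp * np.exp(-0.5 * ((xx - mu) / sigma) ** 2) + off

    amp0 = float(y.max() - y.min())
    mu0 = float(x[np.argmax(y)])
    sigma0 = max((x.max() - x.min()) / 6.0, 1e-6)
    p0 = [amp0, mu0, sigma0] + ([float(y.min())] if baseline else [])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # exact fits trip covariance warnings
            popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        resid = float(np.sum((y - model(x, *p0)) ** 2))
        raise RuntimeError(
            f"Gaussian fit failed to converge (initial residual {resid:.3g})"
        ) from exc
    sigma = abs(float(popt[2]))
    return {
        "amplitude": float(popt[0]),
        "center": float(popt[1]),
        "sigma": sigma,
        "fwhm": FWHM_FACTOR * sigma,
    }
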