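"""Alignment ingestion, conservation profiles, class-discriminative
conservation and motif scanning.

Column positions are always reported through a named reference row: the k-th
ungapped residue of that row gets number ``reference_start + k - 1``, so every
output uses the numbering of the protein the reference row comes from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "ConservationProfile",
    "DifferentialConservationCall",
    "read_alignment",
    "sequence_weights",
    "column_profile",
    "differential_conservation",
    "motif_scan",
    "AA_ORDER",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
GAP_CHARS = "-."


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Gapped sequences of equal width plus a reference row for numbering."""

    ids: list[str]
    seqs: list[str]
    reference_row: str | None = None
    reference_start: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.seqs:
            raise AlignmentError("empty alignment")
        width = len(self.seqs[0])
        for rid, seq in zip(self.ids, self.seqs):
            if len(seq) != width:
                raise AlignmentError(
                    f"row {rid!r} has length {len(seq)}, expected {width}"
                )
            for col, ch in enumerate(seq):
                if ch not in AA_INDEX and ch not in GAP_CHARS:
                    raise AlignmentError(
                        f"row {rid!r}, column {col + 1}: illegal character {ch!r}"
                    )
        if self.reference_row is None:
            self.reference_row = self.ids[0]
        if self.reference_row not in self.ids:
            raise AlignmentError(f"reference row {self.reference_row!r} not present")

    @property
    def width(self) -> int:
        return len(self.seqs[0])

    @property
    def n_rows(self) -> int:
        return len(self.seqs)

    def encoded(self) -> np.ndarray:
        """Rows as int codes: 0..19 for residues, -1 for gap."""
        out = np.full((self.n_rows, self.width), -1, dtype=np.int8)
        for i, seq in enumerate(self.seqs):
            for j, ch in enumerate(seq):
                if ch in AA_INDEX:
                    out[i, j] = AA_INDEX[ch]
        return out

    def column_numbers(self) -> list[int | None]:
        """Reference residue number per column (None where reference is gapped)."""
        ref = self.seqs[self.ids.index(self.reference_row)]
        out: list[int | None] = []
        k = self.reference_start
        for ch in ref:
            if ch in GAP_CHARS:
                out.append(None)
            else:
                out.append(k)
                k += 1
        return out

    def gap_fractions(self) -> np.ndarray:
        enc = self.encoded()
        return (enc < 0).mean(axis=0)


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    reference_row: str | None = None,
    reference_start: int = 1,
) -> Alignment:
    """Read a FASTA or Stockholm alignment; Stockholm #=GC lines become metadata."""
    from Bio import AlignIO

    if format not in ("fasta", "stockholm"):
        raise AlignmentError(f"unknown alignment format {format!r}")
    aln = AlignIO.read(str(path), format)
    ids = [rec.id for rec in aln]
    seqs = [str(rec.seq).upper().replace(".", "-") for rec in aln]
    metadata = {}
    if format == "stockholm" and getattr(aln, "column_annotations", None):
        metadata["column_annotations"] = dict(aln.column_annotations)
    return Alignment(
        ids=ids, seqs=seqs, reference_row=reference_row,
        reference_start=reference_start, metadata=metadata,
    )


def sequence_weights(a: Alignment, identity_threshold: float = 0.8) -> np.ndarray:
    """Inverse-cluster-size weights: w_s = 1 / |{t : id(s,t) >= threshold}|.

    Identity is counted over columns where both rows are ungapped (1.0 for a
    pair with no shared ungapped column, so fully-gapped duplicates cluster).
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    enc = a.encoded()
    n = enc.shape[0]
    nongap = enc >= 0
    counts = np.zeros(n)
    for i in range(n):
        both = nongap[i] & nongap
        shared = both.sum(axis=1)
        match = ((enc[i] == enc) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(shared > 0, match / np.maximum(shared, 1), 1.0)
        counts[i] = np.sum(ident >= identity_threshold)
    return 1.0 / counts


@dataclass
class ConservationProfile:
    frequencies: np.ndarray  # (width, 20), each row sums to 1
    information: np.ndarray  # bits, gap-scaled
    consensus: list[str]
    gap_fraction: np.ndarray
    weights: np.ndarray
    column_numbers: list[int | None]

    def top_frequency(self) -> np.ndarray:
        return self.frequencies.max(axis=1)


def column_profile(
    a: Alignment,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> ConservationProfile:
    """Weighted, pseudocounted per-column frequencies and information content.

    IC per column is (log2 20 - H) * (1 - gap_fraction), H the Shannon entropy
    of the pseudocounted residue frequencies in bits.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    enc = a.encoded()
    n, w = enc.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    freqs = np.zeros((w, 20))
    gapf = np.zeros(w)
    total_w = weights.sum()
    for j in range(w):
        col = enc[:, j]
        mask = col >= 0
        gapf[j] = weights[~mask].sum() / total_w if total_w else 0.0
        counts = np.bincount(col[mask], weights=weights[mask], minlength=20).astype(float)
        counts += pseudocount / 20.0
        tot = counts.sum()
        freqs[j] = counts / tot if tot > 0 else np.full(20, 1 / 20)
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(freqs > 0, np.log2(freqs), 0.0)
    entropy = -(freqs * logf).sum(axis=1)
    ic = (np.log2(20.0) - entropy) * (1.0 - gapf)
    consensus = [AA_ORDER[int(i)] for i in freqs.argmax(axis=1)]
    return ConservationProfile(
        frequencies=freqs, information=ic, consensus=consensus,
        gap_fraction=gapf, weights=weights, column_numbers=a.column_numbers(),
    )


@dataclass
class DifferentialConservationCall:
    column_a: int
    column_b: int
    residue_number: int | None
    call: str  # shared | A-specific | B-specific | unconserved
    consensus_a: str
    consensus_b: str
    top_freq_a: float
    top_freq_b: float


def differential_conservation(
    profile_a: ConservationProfile,
    profile_b: ConservationProfile,
    column_mapping: list[tuple[int, int]] | None = None,
    t_cons: float = 0.7,
    t_var: float = 0.3,
    gap_exclude: float = 0.5,
) -> list[DifferentialConservationCall]:
    """Classify mapped column pairs as shared / A-specific / B-specific / unconserved.

    A column is conserved in a family when its top residue frequency >= t_cons.
    Conserved in both with the same consensus -> shared; with different
    consensus -> specific on both sides (reported A-specific and B-specific
    via a combined "divergent" call on each).  Columns with gap fraction above
    ``gap_exclude`` in either family are skipped.
    """
    if t_cons <= t_var:
        raise ValueError("t_cons must exceed t_var")
    if column_mapping is None:
        if profile_a.frequencies.shape[0] != profile_b.frequencies.shape[0]:
            raise ValueError("profiles differ in width and no mapping given")
        column_mapping = [(j, j) for j in range(profile_a.frequencies.shape[0])]
    calls = []
    for ja, jb in column_mapping:
        if profile_a.gap_fraction[ja] > gap_exclude or profile_b.gap_fraction[jb] > gap_exclude:
            logger.info("skipping gap-rich column pair (%d, %d)", ja, jb)
            continue
        fa = float(profile_a.frequencies[ja].max())
        fb = float(profile_b.frequencies[jb].max())
        ca = profile_a.consensus[ja]
        cb = profile_b.consensus[jb]
        cons_a = fa >= t_cons
        cons_b = fb >= t_cons
        if cons_a and cons_b:
            call = "shared" if ca == cb else "divergent"
        elif cons_a:
            call = "A-specific"
        elif cons_b:
            call = "B-specific"
        else:
            call = "unconserved"
        calls.append(
            DifferentialConservationCall(
                column_a=ja, column_b=jb,
                residue_number=profile_a.column_numbers[ja],
                call=call, consensus_a=ca, consensus_b=cb,
                top_freq_a=fa, top_freq_b=fb,
            )
        )
    return calls


def _parse_pattern(pattern: str) -> list[set[str] | None]:
    """Tokens: single residue, 'x' wildcard, or bracketed class like [ST]."""
    tokens: list[set[str] | None] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            tokens.append(set(pattern[i + 1:j].upper()))
            i = j + 1
        elif ch in "xX.":
            tokens.append(None)
            i += 1
        else:
            tokens.append({ch.upper()})
            i += 1
    return tokens


def motif_scan(
    subject: Alignment | str,
    pattern: str,
    min_support: float = 0.5,
) -> list[dict]:
    """Find consensus-level matches of a position-class pattern.

    For an :class:`Alignment`, the consensus sequence is scanned and each hit
    reports the reference residue number of its start plus the per-position
    fraction of rows satisfying the pattern.  For a plain sequence, start
    positions are 1-based and support is 1.0.
    """
    tokens = _parse_pattern(pattern)
    L = len(tokens)

    def _matches(ch: str, tok: set[str] | None) -> bool:
        return tok is None or ch in tok

    hits = []
    if isinstance(subject, str):
        seq = subject.upper()
        for start in range(len(seq) - L + 1):
            if all(_matches(seq[start + k], tokens[k]) for k in range(L)):
                hits.append({
                    "start": start + 1,
                    "support": [1.0] * L,
                    "consensus": seq[start:start + L],
                })
        return hits

    prof = column_profile(subject, pseudocount=0.0)
    enc = subject.encoded()
    numbers = subject.column_numbers()
    cons = prof.consensus
    w = subject.width
    for start in range(w - L + 1):
        if not all(_matches(cons[start + k], tokens[k]) for k in range(L)):
            continue
        support = []
        for k, tok in enumerate(tokens):
            col = enc[:, start + k]
            valid = col >= 0
            if tok is None:
                support.append(float(valid.mean()))
            else:
                tok_idx = {AA_INDEX[t] for t in tok if t in AA_INDEX}
                support.append(float(np.isin(col, list(tok_idx)).mean()))
        if np.mean([s for t, s in zip(tokens, support) if t is not None]) < min_support:
            continue
        hits.append({
            "start": numbers[start],
            "column": start,
            "support": support,
            "consensus": "".join(cons[start:start + L]),
        })
    return hits
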