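"""Compositional statistics: GC content, codon-usage vectors and their
correlation, and pairwise percent identity (pre-aligned or globally aligned).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CodonUsageVector",
    "gc_content",
    "codon_usage",
    "usage_correlation",
    "percent_identity",
    "reverse_complement",
    "SENSE_CODONS",
    "STOP_CODONS",
]

_BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)
SENSE_CODONS = tuple(c for c in _ALL_CODONS if c not in STOP_CODONS)

_CODON_TABLE = {
    # standard genetic code, sense codons -> amino acid
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                            "TGCAYRMKVHDBNtgcayrmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases: 100*(G+C)/(A+C+G+T).

    Ambiguity codes and gaps count in neither numerator nor denominator.
    """
    s = seq.upper()
    gc = sum(1 for c in s if c in "GC")
    at = sum(1 for c in s if c in "AT")
    if gc + at == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / (gc + at)


@dataclass(frozen=True)
class CodonUsageVector:
    """Codon usage over the 61 sense codons.

    ``mode`` is "overall" (frequencies sum to 1 across sense codons) or
    "rscu" (per-amino-acid relative synonymous codon usage).
    """

    counts: tuple[int, ...]  # raw counts, one per SENSE_CODONS entry
    frequencies: tuple[float, ...]
    mode: str
    cds_count: int
    codon_total: int

    def as_array(self) -> np.ndarray:
        return np.asarray(self.frequencies, dtype=float)


def codon_usage(
    cds_set: list[str], mode: str = "overall", on_internal_stop: str = "warn-skip"
) -> CodonUsageVector:
    """Aggregate codon counts across in-frame coding sequences.

    Each CDS must have length divisible by 3; stop codons are allowed only
    terminally and are excluded from the 61-dimensional vector.  Internal
    stops trigger a warning and skip of the offending CDS by default
    (``on_internal_stop`` may also be "fail").
    """
    if mode not in ("overall", "rscu"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    counts = dict.fromkeys(SENSE_CODONS, 0)
    used = 0
    for idx, cds in enumerate(cds_set):
        s = cds.upper().replace("U", "T")
        if len(s) % 3 != 0:
            raise ValueError(f"CDS #{idx} length {len(s)} not divisible by 3")
        codons = [s[i : i + 3] for i in range(0, len(s), 3)]
        if any(c in STOP_CODONS for c in codons[:-1]):
            msg = f"CDS #{idx} contains an internal stop codon"
            if on_internal_stop == "fail":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for c in codons:
            if c in counts:
                counts[c] += 1
        used += 1

    total = sum(counts.values())
    if mode == "overall":
        freqs = tuple((counts[c] / total) if total else 0.0 for c in SENSE_CODONS)
    else:
        by_aa: dict[str, list[str]] = {}
        for c in SENSE_CODONS:
            by_aa.setdefault(_CODON_TABLE[c], []).append(c)
        rscu = {}
        for aa, codons_aa in by_aa.items():
            aa_total = sum(counts[c] for c in codons_aa)
            k = len(codons_aa)
            for c in codons_aa:
                rscu[c] = (counts[c] * k / aa_total) if aa_total else 0.0
        freqs = tuple(rscu[c] for c in SENSE_CODONS)
    return CodonUsageVector(
        counts=tuple(counts[c] for c in SENSE_CODONS),
        frequencies=freqs,
        mode=mode,
        cds_count=used,
        codon_total=total,
    )


def usage_correlation(
    u: CodonUsageVector, v: CodonUsageVector
) -> tuple[float, float]:
    """Pearson correlation of two codon-usage vectors with its two-sided
    p-value (t transform, n-2 df)."""
    if u.mode != v.mode:
        raise ValueError("codon-usage vectors have different normalization modes")
    x, y = u.as_array(), v.as_array()
    if len(x) != len(y):
        raise ValueError("codon dimension mismatch")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _pairwise_identity_prealigned(a: str, b: str, end_gap_free: bool) -> float:
    if len(a) != len(b):
        raise ValueError("pre-aligned sequences must have equal length")
    a, b = a.upper(), b.upper()

    def span(s: str) -> tuple[int, int]:
        first = next((i for i, c in enumerate(s) if c != "-"), 0)
        last = next((i for i in range(len(s) - 1, -1, -1) if s[i] != "-"), len(s) - 1)
        return first, last

    if end_gap_free:
        fa, la = span(a)
        fb, lb = span(b)
        lo, hi = max(fa, fb), min(la, lb)
    else:
        lo, hi = 0, len(a) - 1
    matches = columns = 0
    for i in range(lo, hi + 1):
        x, y = a[i], b[i]
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    if columns == 0:
        raise ValueError("no aligned columns to compare")
    return 100.0 * matches / columns


def percent_identity(
    a: str,
    b: str,
    mode: str = "global-align",
    end_gap_free: bool = True,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> float:
    """Percent identity between two sequences.

    ``pre-aligned`` mode compares equal-length gapped strings directly;
    ``global-align`` first aligns globally (end gaps free by default).  The
    identity denominator covers aligned columns excluding gap-gap columns
    and, with ``end_gap_free``, terminal overhangs.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if mode == "pre-aligned":
        return _pairwise_identity_prealigned(a, b, end_gap_free)
    if mode != "global-align":
        raise ValueError(f"unknown mode {mode!r}")

    from Bio import Align

    # canonical argument order: identity is symmetric, but co-optimal
    # alignments need not be, so always align the lexicographically smaller
    # sequence first
    if b < a:
        a, b = b, a

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if end_gap_free:
        aligner.end_gap_score = 0.0
    aln = aligner.align(a.upper(), b.upper())[0]
    sa, sb = str(aln[0]), str(aln[1])
    try:
        return _pairwise_identity_prealigned(sa, sb, end_gap_free)
    except ValueError:
        return 0.0  # optimal alignment has no overlapping columns
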