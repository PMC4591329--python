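"""Nucleotide composition and strand-asymmetry (skew) statistics.

Metazoan mitochondrial genomes show a pronounced strand bias: the two
strands differ in A vs T and G vs C content, quantified by the signed skews

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

both dimensionless in [-1, 1] and scale-invariant (percentages or raw counts
give the same value).  This module computes base counts, skews and composite
summaries for whole genomes, pooled feature classes (per kind and/or strand,
always on each feature's sense strand), and the three codon positions of
protein-coding genes.

Ambiguous (non-ACGT) bases are tallied separately and excluded from every
numerator and denominator.  U is counted as T.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .genome_model import (
    CONTROL_REGION,
    GenomeAnnotation,
    SequenceRecord,
    feature_length,
)

__all__ = [
    "BaseCounts",
    "CompositionSummary",
    "base_counts",
    "at_skew",
    "gc_skew",
    "summarize",
    "class_composition",
    "codon_position_composition",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (tables round 0.5 away from zero)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BaseCounts:
    """Raw base tallies of one sequence or pooled sequence set."""

    A: int = 0
    C: int = 0
    G: int = 0
    T: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        """Unambiguous total (A+C+G+T)."""
        return self.A + self.C + self.G + self.T

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.A + other.A, self.C + other.C,
                          self.G + other.G, self.T + other.T,
                          self.ambiguous + other.ambiguous)


@dataclass(frozen=True)
class CompositionSummary:
    """Percent composition and skews of one sequence class.

    Percentages are carried unrounded; table-style formatting applies
    1-decimal (percent) / 2- or 3-decimal (skew) half-up rounding.
    """

    counts: BaseCounts
    pct_T: float
    pct_C: float
    pct_A: float
    pct_G: float
    pct_AT: float
    pct_GC: float
    at_skew: Optional[float]
    gc_skew: Optional[float]

    def rounded(self, skew_decimals: int = 2) -> dict[str, Optional[float]]:
        r = lambda v: round_half_up(v, 1)
        rs = lambda v: None if v is None else round_half_up(v, skew_decimals)
        return {
            "%T": r(self.pct_T), "%C": r(self.pct_C),
            "%A": r(self.pct_A), "%G": r(self.pct_G),
            "%A+T": r(self.pct_AT), "%G+C": r(self.pct_GC),
            "AT_skew": rs(self.at_skew), "GC_skew": rs(self.gc_skew),
        }


def base_counts(s: str) -> BaseCounts:
    """Tally A/C/G/T in a nucleotide string; U counts as T.

    Any other character (IUPAC ambiguity, N, gaps) is tallied as ambiguous.
    Raises ``ValueError`` on an empty sequence.
    """
    if not s:
        raise ValueError("empty sequence")
    c = Counter(s.upper())
    a, cc, g = c["A"], c["C"], c["G"]
    t = c["T"] + c["U"]
    return BaseCounts(A=a, C=cc, G=g, T=t,
                      ambiguous=len(s) - (a + cc + g + t))


def at_skew(a: float, t: float) -> Optional[float]:
    """(A - T)/(A + T); ``None`` when A + T == 0."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> Optional[float]:
    """(G - C)/(G + C); ``None`` when G + C == 0."""
    if g + c == 0:
        return None
    return (g - c) / (g + c)


def summarize(counts: BaseCounts) -> CompositionSummary:
    """Percentages and skews from raw counts (ambiguous bases excluded)."""
    n = counts.total
    if n == 0:
        raise ValueError("no unambiguous bases to summarize")
    p = lambda x: 100.0 * x / n
    return CompositionSummary(
        counts=counts,
        pct_T=p(counts.T), pct_C=p(counts.C),
        pct_A=p(counts.A), pct_G=p(counts.G),
        pct_AT=p(counts.A + counts.T), pct_GC=p(counts.G + counts.C),
        at_skew=at_skew(counts.A, counts.T),
        gc_skew=gc_skew(counts.G, counts.C),
    )


def class_composition(
    genome: SequenceRecord,
    a: GenomeAnnotation,
    kinds: Optional[Sequence[str]] = None,
    strand: Optional[str] = None,
) -> CompositionSummary:
    """Pooled composition of a feature class.

    Selects features by ``kinds`` (e.g. ``["PCG"]``) and/or ``strand``
    (``"J"``/``"N"``); with both ``None`` the whole genome's stored J strand
    is summarized directly.  Selected features contribute their *sense*
    strand sequence (N-strand features reverse-complemented), so e.g. the
    PCG-N class reports the composition the genes are actually read in.
    Nucleotides shared by overlapping features count once per feature.
    """
    if kinds is None and strand is None:
        return summarize(base_counts(genome.seq))
    sel = [f for f in a.features
           if (kinds is None or f.kind in kinds)
           and (strand is None or f.strand == strand)]
    if not sel:
        raise ValueError(
            f"no features match filter kinds={kinds!r} strand={strand!r}")
    total = BaseCounts()
    for f in sel:
        total = total + base_counts(genome.feature_seq(f))
    return summarize(total)


def codon_position_composition(
    cds_list: Iterable[str],
) -> dict[int, CompositionSummary]:
    """Per-codon-position composition pooled over in-frame coding sequences.

    Each input must already be a sense-strand CDS starting in frame (4-nt
    quadruplet starts removed, see the codon_usage module); a trailing
    incomplete codon is ignored.  Returns summaries keyed 1, 2, 3.
    """
    import warnings

    pooled = {1: BaseCounts(), 2: BaseCounts(), 3: BaseCounts()}
    for cds in cds_list:
        if len(cds) < 3:
            warnings.warn(f"skipping coding sequence of length {len(cds)} < 3")
            continue
        usable = len(cds) - len(cds) % 3
        for pos in (1, 2, 3):
            pooled[pos] = pooled[pos] + base_counts(cds[pos - 1:usable:3])
    if pooled[1].total == 0:
        raise ValueError("no usable codons in input")
    return {pos: summarize(c) for pos, c in pooled.items()}
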