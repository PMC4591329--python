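"""Control-region structural-element scanners.

The mitochondrial control region (A+T-rich region) carries short sequence
elements implicated in replication and transcription initiation.  Three
classes are scanned here, each strand-aware:

* **poly-T stretches** — maximal runs of T of at least ``min_run`` bases;
* **(TA)n stretches** — maximal TA-periodic runs reported as n complete TA
  units (phase-agnostic: an AT-phased run is reported in the TA frame that
  maximizes n);
* **G(A)nT motifs** — a G, a maximal run of ≥ ``min_a`` A's, then a T.

Hits are reported in a single coordinate system — the input (J) strand,
1-based inclusive — with a strand flag; an N-strand hit is found on the
reverse complement and its coordinates mapped back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional

from .genome_model import (
    GenomeAnnotation,
    SequenceRecord,
    feature_length,
    revcomp,
)

__all__ = [
    "POLY_T",
    "TA_REPEAT",
    "GANT",
    "MotifHit",
    "ScanConfig",
    "find_poly_t",
    "find_ta_repeats",
    "find_gant",
    "scan_control_region",
]

POLY_T = "polyT"
TA_REPEAT = "TA_repeat"
GANT = "GAnT"


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, in J-strand 1-based inclusive coordinates.

    ``n`` is the repeat count: number of TA units for (TA)n, number of A's
    for G(A)nT, and the run length itself for poly-T.
    """

    motif: str
    start: int
    end: int
    strand: str
    n: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _flip(hits: list[MotifHit], length: int) -> list[MotifHit]:
    """Map hits found on the reverse complement back to input coordinates."""
    out = [replace(h, start=length - h.end + 1, end=length - h.start + 1,
                   strand="N")
           for h in hits]
    return sorted(out, key=lambda h: h.start)


def find_poly_t(s: str, min_run: int = 10, strand: str = "J") -> list[MotifHit]:
    """Maximal runs of T with length >= min_run, sorted by start.

    ``strand="N"`` scans the reverse complement (i.e. reports poly-T runs of
    the opposite strand, which read as poly-A on the input) with coordinates
    mapped back to the input strand.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if strand == "N":
        return _flip(find_poly_t(revcomp(s), min_run), len(s))
    s = s.upper().replace("U", "T")
    hits = [MotifHit(POLY_T, m.start() + 1, m.end(), "J", m.end() - m.start())
            for m in re.finditer(rf"T{{{min_run},}}", s)]
    return hits


def find_ta_repeats(s: str, min_units: int = 5, strand: str = "J"
                    ) -> list[MotifHit]:
    """Maximal (TA)-periodic runs with at least ``min_units`` TA units.

    Each maximal strictly-alternating T/A run is reported once, in the TA
    frame that maximizes the unit count n; length = 2n.
    """
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    if strand == "N":
        return _flip(find_ta_repeats(revcomp(s), min_units), len(s))
    s = s.upper().replace("U", "T")
    hits: list[MotifHit] = []
    # maximal alternating runs: no TT/AA inside, bounded by run maximality
    for m in re.finditer(r"(?:TA)+T?|A(?:TA)*T?", s):
        run = m.group(0)
        if len(run) < 2:
            continue
        off = 1 if run[0] == "A" else 0  # shift into TA frame
        n = (len(run) - off) // 2
        if n >= min_units:
            start = m.start() + off + 1
            hits.append(MotifHit(TA_REPEAT, start, start + 2 * n - 1, "J", n))
    return hits


def find_gant(s: str, min_a: int = 1, strand: str = "J") -> list[MotifHit]:
    """Occurrences of G(A)nT with a maximal A-run of >= min_a, in order.

    Hits are non-overlapping within their G..T span (left-to-right greedy).
    """
    if min_a < 1:
        raise ValueError("min_a must be >= 1")
    if strand == "N":
        return _flip(find_gant(revcomp(s), min_a), len(s))
    s = s.upper().replace("U", "T")
    return [MotifHit(GANT, m.start() + 1, m.end(), "J", m.end() - m.start() - 2)
            for m in re.finditer(rf"GA{{{min_a},}}T", s)]


@dataclass(frozen=True)
class ScanConfig:
    """Detection thresholds for the three scanners (config-overridable)."""

    min_poly_t: int = 10
    min_ta_units: int = 5
    min_gant_a: int = 1


def scan_control_region(genome: SequenceRecord, a: GenomeAnnotation,
                        config: Optional[ScanConfig] = None) -> list[MotifHit]:
    """Scan the annotated control region on both strands.

    Returns all three motif classes from both strand readings, with genome
    (J-strand, 1-based) coordinates and strand flags, sorted by position.
    Raises ``ValueError`` if no control region is annotated.
    """
    config = config or ScanConfig()
    cr = a.control_region
    if cr is None:
        raise ValueError("annotation contains no control region")
    seq = genome.slice(cr.start, cr.end)  # J strand of the CR
    hits: list[MotifHit] = []
    for strand in ("J", "N"):
        hits += find_poly_t(seq, config.min_poly_t, strand)
        hits += find_ta_repeats(seq, config.min_ta_units, strand)
        hits += find_gant(seq, config.min_gant_a, strand)
    n = a.genome_length
    out = [replace(h, start=(cr.start + h.start - 2) % n + 1,
                   end=(cr.start + h.end - 2) % n + 1)
           for h in hits]
    return sorted(out, key=lambda h: (h.start, h.motif, h.strand))
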