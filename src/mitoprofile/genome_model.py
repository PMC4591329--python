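"""Data model and I/O for circular mitochondrial genome annotations.

A mitogenome annotation is an *ordered* table of features on a circular
molecule: 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one
non-coding control region in the canonical dipteran arrangement.  Features
live on one of two strands: the majority (J) strand, written ``F`` in
annotation tables, or the minority (N) strand, written ``R``.  Coordinates
are 1-based inclusive on the J strand throughout all I/O.

The geometry statistics computed here are the classic descriptive numbers of
a mitogenome report: intergenic spacers (positive gaps between consecutive
features), gene overlaps (negative gaps), and the per-strand gene tally.
Because the molecule is circular, the pair (last feature, first feature) is a
consecutive pair like any other, and a feature whose end coordinate is lower
than its start wraps the origin.
"""

from __future__ import annotations

import importlib.resources
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "PCG",
    "TRNA",
    "RRNA",
    "CONTROL_REGION",
    "GeneFeature",
    "GenomeAnnotation",
    "GeometrySummary",
    "SequenceRecord",
    "AnnotationParseError",
    "parse_annotation_table",
    "write_annotation_table",
    "read_genbank",
    "load_reference_annotation",
    "feature_length",
    "intergenic_gap",
    "geometry_summary",
    "strand_tally",
]

# Feature kinds
PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (IUPAC-aware, U→A)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationParseError(ValueError):
    """Raised when an annotation table cannot be parsed; names the row."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the circular J strand.

    ``start`` and ``end`` are 1-based inclusive J-strand coordinates; a
    feature with ``end < start`` wraps the origin.  ``strand`` is ``"J"`` or
    ``"N"``.  ``anticodon_span`` (tRNAs only) is a 1-based inclusive J-strand
    coordinate pair; ``anticodon`` is the anticodon read on the tRNA's own
    sense strand.  ``start_codon`` may be a 4-nt quadruplet (COI's ATCA) and
    ``stop_codon`` may be an incomplete "T" or "TA".
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int
    anticodon_span: Optional[tuple[int, int]] = None
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    declared_size: Optional[int] = None
    declared_gap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N")
        if self.kind not in (PCG, TRNA, RRNA, CONTROL_REGION):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start


@dataclass(frozen=True)
class GenomeAnnotation:
    """Ordered feature table of one circular mitogenome."""

    features: tuple[GeneFeature, ...]
    genome_length: int

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("annotation has no features")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_kind(self, *kinds: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.kind in kinds)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def control_region(self) -> Optional[GeneFeature]:
        crs = self.by_kind(CONTROL_REGION)
        return crs[0] if crs else None


@dataclass(frozen=True)
class SequenceRecord:
    """One strand (the J strand) of a circular nucleotide sequence."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive circular slice on the stored (J) strand."""
        n = len(self.seq)
        if not (1 <= start <= n and 1 <= end <= n):
            raise IndexError(f"slice {start}-{end} outside 1-{n}")
        if end >= start:
            return self.seq[start - 1 : end]
        return self.seq[start - 1 :] + self.seq[:end]

    def feature_seq(self, f: GeneFeature) -> str:
        """Sense-strand (reading-strand) sequence of a feature."""
        s = self.slice(f.start, f.end)
        return revcomp(s) if f.strand == "N" else s


@dataclass(frozen=True)
class GapRecord:
    """Signed gap between two consecutive features (circular order)."""

    prev: str
    next: str
    gap: int  # >0 spacer, <0 overlap, 0 abutting


@dataclass(frozen=True)
class GeometrySummary:
    """Spacer/overlap census and strand tally of an annotation."""

    gaps: tuple[GapRecord, ...]
    spacers: tuple[GapRecord, ...]
    overlaps: tuple[GapRecord, ...]
    spacer_count: int
    spacer_total_bp: int
    spacer_max_bp: int
    overlap_count: int
    overlap_total_bp: int
    overlap_max_bp: int
    strand_tally: dict[str, tuple[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry arithmetic


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature, honouring origin wrap-around."""
    if f.end >= f.start:
        return f.end - f.start + 1
    return genome_length - f.start + 1 + f.end


def intergenic_gap(prev: GeneFeature, nxt: GeneFeature, genome_length: int) -> int:
    """Signed gap between two features consecutive in annotation order.

    Positive = intergenic spacer, negative = overlap, 0 = abutting.  The
    last→first pair is handled circularly (gap computed modulo the circle,
    mapped into the smallest-magnitude representation around the origin).
    """
    gap = nxt.start - prev.end - 1
    if gap < -genome_length // 2:
        gap += genome_length
    elif gap > genome_length // 2:
        gap -= genome_length
    return gap


def geometry_summary(a: GenomeAnnotation) -> GeometrySummary:
    """Classify every consecutive pair (incl. circular last→first).

    Convention: the gap belongs to the *following* feature's row, matching
    the usual mitogenome organization-table layout.
    """
    feats = a.features
    gaps: list[GapRecord] = []
    n = len(feats)
    if n == 1:
        f = feats[0]
        # single feature: the only pair is (f, f); a full-circle feature
        # leaves neither spacer nor overlap.
        leftover = a.genome_length - feature_length(f, a.genome_length)
        if leftover:
            gaps.append(GapRecord(f.name, f.name, leftover))
    else:
        for i in range(n):
            prev, nxt = feats[i], feats[(i + 1) % n]
            g = intergenic_gap(prev, nxt, a.genome_length)
            gaps.append(GapRecord(prev.name, nxt.name, g))
    spacers = tuple(g for g in gaps if g.gap > 0)
    overlaps = tuple(g for g in gaps if g.gap < 0)
    return GeometrySummary(
        gaps=tuple(gaps),
        spacers=spacers,
        overlaps=overlaps,
        spacer_count=len(spacers),
        spacer_total_bp=sum(g.gap for g in spacers),
        spacer_max_bp=max((g.gap for g in spacers), default=0),
        overlap_count=len(overlaps),
        overlap_total_bp=sum(-g.gap for g in overlaps),
        overlap_max_bp=max((-g.gap for g in overlaps), default=0),
        strand_tally=strand_tally(a),
    )


def strand_tally(a: GenomeAnnotation) -> dict[str, tuple[int, int]]:
    """Per-kind (J count, N count); the control region is not a gene.

    The returned mapping has one entry per gene kind present plus a
    ``"genes"`` total over PCG+tRNA+rRNA.
    """
    tally: dict[str, list[int]] = {}
    for f in a.features:
        if f.kind == CONTROL_REGION:
            continue
        j, n = tally.setdefault(f.kind, [0, 0])
        if f.strand == "J":
            tally[f.kind][0] += 1
        else:
            tally[f.kind][1] += 1
    out = {k: (v[0], v[1]) for k, v in tally.items()}
    out["genes"] = (
        sum(v[0] for k, v in out.items()),
        sum(v[1] for k, v in out.items()),
    )
    return out


# ---------------------------------------------------------------------------
# Annotation table I/O (organization-table TSV dialect)

_LOCATION_RE = re.compile(r"^\s*(\d+)\s*[–\-]\s*(\d+)\s*$")
_ANTICODON_RE = re.compile(r"^\s*(\d+)\s*[–\-]\s*(\d+)\s*([ACGTU]{3})\s*$", re.I)

_HEADER = ["Gene", "Direction", "Location", "Size", "Anticodon", "Start",
           "Stop", "Intergenic"]


def infer_kind(name: str) -> str:
    low = name.lower()
    if low.startswith("trna") or low.startswith("trn"):
        return TRNA
    if "rrna" in low or low in ("srrna", "lrrna", "12s", "16s"):
        return RRNA
    if "control" in low or "d-loop" in low or "a+t" in low:
        return CONTROL_REGION
    return PCG


def parse_annotation_table(text: str) -> GenomeAnnotation:
    """Parse an organization-table TSV into a :class:`GenomeAnnotation`.

    Expected columns: Gene, Direction (F/R; may be blank for the control
    region), Location ("a-b" or "a–b"), Size, Anticodon ("p-qXXX"), Start,
    Stop, Intergenic.  The Intergenic column is retained for cross-checking
    but recomputed values take precedence.  Genome length is the maximum end
    coordinate.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AnnotationParseError("no features: empty table")
    header = [h.strip() for h in lines[0].split("\t")]
    idx = {h.lower(): i for i, h in enumerate(header)}
    if "gene" not in idx or "location" not in idx:
        raise AnnotationParseError("header must contain Gene and Location columns")

    def cell(row: list[str], col: str) -> str:
        i = idx.get(col)
        return row[i].strip() if i is not None and i < len(row) else ""

    feats: list[GeneFeature] = []
    for rowno, ln in enumerate(lines[1:], start=2):
        row = ln.split("\t")
        name = cell(row, "gene")
        if not name:
            raise AnnotationParseError(f"row {rowno}: empty gene name")
        m = _LOCATION_RE.match(cell(row, "location"))
        if not m:
            raise AnnotationParseError(
                f"row {rowno} ({name}): malformed location "
                f"{cell(row, 'location')!r}")
        start, end = int(m.group(1)), int(m.group(2))
        kind = infer_kind(name)
        direction = cell(row, "direction")
        if direction == "" and kind == CONTROL_REGION:
            strand = "J"  # the non-coding region carries no direction
        elif direction == "F":
            strand = "J"
        elif direction == "R":
            strand = "N"
        else:
            raise AnnotationParseError(
                f"row {rowno} ({name}): direction must be F or R, "
                f"got {direction!r}")
        ac_span = ac_seq = None
        ac_cell = cell(row, "anticodon")
        if ac_cell:
            am = _ANTICODON_RE.match(ac_cell)
            if not am:
                raise AnnotationParseError(
                    f"row {rowno} ({name}): malformed anticodon {ac_cell!r}")
            ac_span = (int(am.group(1)), int(am.group(2)))
            ac_seq = am.group(3).upper()
        size_cell = cell(row, "size")
        gap_cell = cell(row, "intergenic")
        feats.append(GeneFeature(
            name=name, kind=kind, strand=strand, start=start, end=end,
            anticodon_span=ac_span, anticodon=ac_seq,
            start_codon=cell(row, "start") or None,
            stop_codon=cell(row, "stop") or None,
            declared_size=int(size_cell) if size_cell else None,
            declared_gap=int(gap_cell) if gap_cell else None,
        ))
    if not feats:
        raise AnnotationParseError("no features")
    genome_length = max(f.end for f in feats)
    return GenomeAnnotation(features=tuple(feats), genome_length=genome_length)


def write_annotation_table(a: GenomeAnnotation) -> str:
    """Serialize back to the organization-table TSV dialect."""
    out = io.StringIO()
    out.write("\t".join(_HEADER) + "\n")
    for f in a.features:
        ac = ""
        if f.anticodon_span:
            ac = f"{f.anticodon_span[0]}-{f.anticodon_span[1]}{f.anticodon or ''}"
        cells = [
            f.name,
            {"J": "F", "N": "R"}[f.strand] if f.kind != CONTROL_REGION else "",
            f"{f.start}-{f.end}",
            str(f.declared_size
                if f.declared_size is not None
                else feature_length(f, a.genome_length)),
            ac,
            f.start_codon or "",
            f.stop_codon or "",
            "" if f.declared_gap is None else str(f.declared_gap),
        ]
        out.write("\t".join(cells).rstrip("\t ") + "\n")
    return out.getvalue()


def load_reference_annotation() -> GenomeAnnotation:
    """The bundled *Delia antiqua* organization table (KT026595 layout)."""
    text = (importlib.resources.files("mitoprofile")
            .joinpath("data/delia_antiqua_annotation.tsv")
            .read_text())
    return parse_annotation_table(text)


# ---------------------------------------------------------------------------
# GenBank flat-file input

_GB_KIND = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA}


def read_genbank(handle) -> tuple[SequenceRecord, GenomeAnnotation]:
    """Read a GenBank flat file into (sequence, annotation).

    Maps CDS/tRNA/rRNA features and misc_feature/D-loop (control region) to
    :class:`GeneFeature`; other feature types are ignored.  ``handle`` may be
    a path or an open text handle.
    """
    from Bio import SeqIO

    rec = SeqIO.read(handle, "genbank")
    feats: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type in _GB_KIND:
            kind = _GB_KIND[feat.type]
        elif feat.type in ("misc_feature", "D-loop"):
            kind = CONTROL_REGION
        else:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product")
                or quals.get("note") or [feat.type])[0]
        strand = "N" if feat.location.strand == -1 else "J"
        start = int(feat.location.start) + 1  # 0-based → 1-based
        end = int(feat.location.end)
        feats.append(GeneFeature(name=name, kind=kind, strand=strand,
                                 start=start, end=end))
    feats.sort(key=lambda f: f.start)
    seq = SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
    return seq, GenomeAnnotation(features=tuple(feats),
                                 genome_length=len(seq.seq))
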