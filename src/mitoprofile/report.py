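"""Assemble the full five-table mitogenome report and comparative exports.

``build_report`` orchestrates every analysis stage — gene geometry, class
and codon-position composition, codon usage/RSCU, amino-acid percentages,
tRNA clover-leaf structures and control-region motifs — into one
:class:`MitogenomeReport` of pandas DataFrames mirroring the standard
mitogenome-paper table layouts.  A failure in one stage is recorded and does
not abort the others.  ``skew_scatter`` produces the comparative
one-row-per-genome AT%/AT-skew/GC%/GC-skew export used for strand-bias
scatter plots across taxa.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .composition import (
    class_composition,
    codon_position_composition,
    round_half_up,
    summarize,
    base_counts,
)
from .codon_usage import codon_usage_table, in_frame_cds
from .cr_motifs import ScanConfig, scan_control_region
from .genome_model import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    GenomeAnnotation,
    SequenceRecord,
    feature_length,
    geometry_summary,
)
from .trna_structure import fold_annotated, mismatch_census

__all__ = ["MitogenomeReport", "build_report", "skew_scatter"]


@dataclass
class MitogenomeReport:
    """All report tables plus a provenance block and per-stage errors."""

    organization: Optional[pd.DataFrame] = None
    composition: Optional[pd.DataFrame] = None
    amino_acids: Optional[pd.DataFrame] = None
    rscu: Optional[pd.DataFrame] = None
    trna_structures: Optional[pd.DataFrame] = None
    cr_motifs: Optional[pd.DataFrame] = None
    geometry: Optional[object] = None
    provenance: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    @property
    def tables(self) -> dict[str, Optional[pd.DataFrame]]:
        return {"organization": self.organization,
                "composition": self.composition,
                "amino_acids": self.amino_acids,
                "rscu": self.rscu,
                "trna_structures": self.trna_structures,
                "cr_motifs": self.cr_motifs}

    def write_tsv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            if df is not None:
                df.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _organization_table(a: GenomeAnnotation) -> pd.DataFrame:
    geom = geometry_summary(a)
    gap_for = {g.next: g.gap for g in geom.gaps}
    rows = []
    for i, f in enumerate(a.features):
        rows.append({
            "Gene": f.name,
            "Direction": "" if f.kind == CONTROL_REGION
                         else {"J": "F", "N": "R"}[f.strand],
            "Location": f"{f.start}-{f.end}",
            "Size": feature_length(f, a.genome_length),
            "Anticodon": (f"{f.anticodon_span[0]}-{f.anticodon_span[1]}"
                          f"{f.anticodon or ''}") if f.anticodon_span else "",
            "Start": f.start_codon or "",
            "Stop": f.stop_codon or "",
            "Intergenic": "" if i == 0 else gap_for.get(f.name, ""),
        })
    return pd.DataFrame(rows)


_COMPOSITION_ROWS = [
    ("Whole genome", None, None),
    ("Protein-coding genes", [PCG], None),
    ("Protein-coding genes-J", [PCG], "J"),
    ("Protein-coding genes-N", [PCG], "N"),
    ("tRNA genes", [TRNA], None),
    ("tRNA genes-J", [TRNA], "J"),
    ("tRNA genes-N", [TRNA], "N"),
    ("rRNA genes", [RRNA], None),
    ("Control region", [CONTROL_REGION], None),
]


def _composition_table(genome: SequenceRecord, a: GenomeAnnotation,
                       raw: bool = False) -> pd.DataFrame:
    rows = []

    def add(label: str, summ) -> None:
        vals = ({"%T": summ.pct_T, "%C": summ.pct_C, "%A": summ.pct_A,
                 "%G": summ.pct_G, "%A+T": summ.pct_AT, "%G+C": summ.pct_GC,
                 "AT_skew": summ.at_skew, "GC_skew": summ.gc_skew}
                if raw else summ.rounded(skew_decimals=2))
        rows.append({"Feature": label, **vals})

    for label, kinds, strand in _COMPOSITION_ROWS:
        try:
            add(label, class_composition(genome, a, kinds, strand))
        except ValueError:
            continue  # class with no members in this annotation
    cds = list(in_frame_cds(genome, a).values())
    if cds:
        for pos, summ in codon_position_composition(cds).items():
            add(f"Codon position {pos}", summ)
    return pd.DataFrame(rows)


def _aa_table(genome: SequenceRecord, a: GenomeAnnotation) -> pd.DataFrame:
    pooled = codon_usage_table(genome, a).aa_percent
    by_j = codon_usage_table(genome, a, strand="J").aa_percent
    by_n = codon_usage_table(genome, a, strand="N").aa_percent
    aas = sorted(set(pooled) | set(by_j) | set(by_n))
    return pd.DataFrame([{
        "AA": aa,
        "Protein-coding genes": round_half_up(pooled.get(aa, 0.0), 2),
        "Protein-coding genes-J": round_half_up(by_j.get(aa, 0.0), 2),
        "Protein-coding genes-N": round_half_up(by_n.get(aa, 0.0), 2),
    } for aa in aas])


def _rscu_table(genome: SequenceRecord, a: GenomeAnnotation) -> pd.DataFrame:
    tab = codon_usage_table(genome, a)
    rows = []
    for codon in sorted(tab.rscu):
        val = tab.rscu[codon]
        rows.append({"Codon": codon,
                     "AA": tab.code.residue(codon),
                     "Count": tab.counts.get(codon, 0),
                     "RSCU": None if val is None else round_half_up(val, 2)})
    return pd.DataFrame(rows)


def _trna_table(genome: SequenceRecord, a: GenomeAnnotation) -> pd.DataFrame:
    rows = []
    for f in a.by_kind(TRNA):
        if f.anticodon_span is None:
            continue
        leaf = fold_annotated(genome, a, f)
        rows.append({
            "tRNA": f.name,
            "Length": len(leaf.seq),
            "Anticodon": leaf.anticodon.replace("T", "U"),
            "Acceptor": leaf.acceptor_stem,
            "DHU": leaf.dhu_stem,
            "AnticodonArm": leaf.anticodon_stem,
            "TPC": leaf.tpc_stem,
            "Mismatches": ";".join(
                f"{m.pos5}:{m.pos3}:{m.pair_type}" for m in leaf.mismatches),
        })
    return pd.DataFrame(rows)


def _motif_table(genome: SequenceRecord, a: GenomeAnnotation,
                 scan: ScanConfig) -> pd.DataFrame:
    hits = scan_control_region(genome, a, scan)
    return pd.DataFrame([{"Motif": h.motif, "Start": h.start, "End": h.end,
                          "Strand": h.strand, "Length": h.length, "n": h.n}
                         for h in hits])


def build_report(genome: SequenceRecord, a: GenomeAnnotation,
                 scan: Optional[ScanConfig] = None,
                 raw: bool = False) -> MitogenomeReport:
    """Run every stage; stage errors are recorded, not raised.

    Raises ``ValueError`` before any stage runs if annotation coordinates
    exceed the genome length.
    """
    bad = [f.name for f in a.features
           if max(f.start, f.end) > len(genome.seq)]
    if bad or a.genome_length != len(genome.seq):
        raise ValueError(
            f"genome/annotation inconsistent: sequence length "
            f"{len(genome.seq)}, annotation length {a.genome_length}, "
            f"out-of-range features {bad}")
    rep = MitogenomeReport(provenance={
        "genome_id": genome.id,
        "genome_length": len(genome.seq),
        "n_features": len(a.features),
        "mitoprofile_version": __version__,
        "scan_config": vars(scan) if scan else vars(ScanConfig()),
    })
    stages = {
        "organization": lambda: _organization_table(a),
        "composition": lambda: _composition_table(genome, a, raw),
        "amino_acids": lambda: _aa_table(genome, a),
        "rscu": lambda: _rscu_table(genome, a),
        "trna_structures": lambda: _trna_table(genome, a),
        "cr_motifs": lambda: _motif_table(genome, a, scan or ScanConfig()),
    }
    for name, stage in stages.items():
        try:
            setattr(rep, name, stage())
        except Exception as exc:  # stage isolation is the contract
            rep.errors[name] = f"{type(exc).__name__}: {exc}"
    try:
        rep.geometry = geometry_summary(a)
    except Exception as exc:
        rep.errors["geometry"] = f"{type(exc).__name__}: {exc}"
    return rep


def skew_scatter(genomes: Sequence[tuple[str, SequenceRecord]],
                 groups: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """One whole-genome composition row per genome (strand-bias scatter).

    Columns: label, %A+T, AT_skew, %G+C, GC_skew, group.  Values are
    computed on the full stored (J) strand of each genome.
    """
    if not genomes:
        raise ValueError("no genomes given")
    rows = []
    for label, rec in genomes:
        s = summarize(base_counts(rec.seq))
        rows.append({
            "label": label,
            "%A+T": round_half_up(s.pct_AT, 1),
            "AT_skew": round_half_up(s.at_skew, 3),
            "%G+C": round_half_up(s.pct_GC, 1),
            "GC_skew": round_half_up(s.gc_skew, 3),
            "group": (groups or {}).get(label, ""),
        })
    return pd.DataFrame(rows)
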