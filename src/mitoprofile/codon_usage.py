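"""Codon extraction, translation (invertebrate mitochondrial code) and
relative synonymous codon usage (RSCU).

Insect mitochondrial PCGs translate under NCBI genetic code table 5, where
AGA/AGG encode Ser (an eight-codon Ser family), UGA encodes Trp and AUA
encodes Met; only UAA/UAG are stops.  Mitogenome annotations bring two
idiosyncrasies handled here explicitly:

* quadruplet starts — COI in many Diptera initiates at a 4-nt signal such as
  ATCA; the quadruplet is consumed whole and excluded from codon statistics
  (it is not a codon), leaving the remainder in frame;
* incomplete stops — a terminal T or TA, completed to UAA by
  polyadenylation after transcript cleavage, is excluded from codon counts,
  whereas complete stop codons are counted as members of the two-codon
  UAA/UAG STOP family.

RSCU(c) = count(c) × k / Σ_family counts, with k the synonymous-family size;
values in a family with any usage sum exactly to k, and an unused family's
RSCU is undefined (reported missing, not 0).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data import CodonTable

from .genome_model import PCG, GenomeAnnotation, SequenceRecord, feature_length

__all__ = [
    "STOP",
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "CodonUsageTable",
    "extract_codons",
    "translate",
    "rscu",
    "aa_composition",
    "gene_codons",
    "codon_usage_table",
]

STOP = "*"

_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr", STOP: "STOP",
}


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A codon→residue map plus its synonymous-family structure.

    ``table`` maps all 64 RNA-alphabet codons to one-letter residues with
    ``"*"`` for STOP.  ``families`` groups codons by residue (STOP included
    as its own family).
    """

    id: int
    name: str
    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError("genetic code must map 64 codons")

    def residue(self, codon: str) -> str:
        """One-letter residue for a codon (DNA or RNA); 'X' if ambiguous."""
        return self.table.get(to_rna(codon), "X")

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        fam: dict[str, list[str]] = {}
        for codon, aa in self.table.items():
            fam.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in fam.items()}

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.residue(codon)]


def _load_table5() -> GeneticCode:
    tbl = CodonTable.unambiguous_rna_by_id[5]
    mapping = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        mapping[stop] = STOP
    return GeneticCode(id=5, name="invertebrate mitochondrial", table=mapping)


#: NCBI translation table 5 — the code used by insect mitochondria.
INVERTEBRATE_MITO = _load_table5()


def extract_codons(cds: str, start_codon: str, stop_codon: str) -> list[str]:
    """Split a sense-strand CDS into codons under annotation conventions.

    ``start_codon`` must be a prefix of ``cds``.  A 4-nt start is consumed
    and not returned; a 3-nt start is returned as an ordinary first codon.
    A declared incomplete stop ("T"/"TA") is trimmed from the end and not
    returned; a complete stop stays as the final codon.  Raises
    ``ValueError`` if the declared start is not a prefix or the remaining
    length is not a multiple of 3.
    """
    cds = cds.upper()
    start_codon = (start_codon or "").upper()
    stop_codon = (stop_codon or "").upper()
    if start_codon and not cds.startswith(start_codon):
        raise ValueError(
            f"declared start codon {start_codon!r} is not a prefix of the CDS")
    body = cds[4:] if len(start_codon) == 4 else cds
    if len(stop_codon) in (1, 2):
        if not body.endswith(stop_codon):
            raise ValueError(
                f"declared incomplete stop {stop_codon!r} does not terminate the CDS")
        body = body[: -len(stop_codon)]
    if len(body) % 3 != 0:
        raise ValueError(
            f"coding length {len(body)} not divisible by 3 after start/stop handling")
    return [body[i:i + 3] for i in range(0, len(body), 3)]


def translate(codons: Iterable[str],
              code: GeneticCode = INVERTEBRATE_MITO) -> str:
    """Residue string (one-letter; '*' = STOP, 'X' = ambiguous codon)."""
    return "".join(code.residue(c) for c in codons)


def rscu(counts: Mapping[str, int],
         code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, Optional[float]]:
    """Relative synonymous codon usage for every codon of the code.

    Keys are RNA-alphabet codons (input accepted in DNA or RNA).  A codon in
    a family with zero total usage maps to ``None``.
    """
    norm = Counter()
    for codon, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {codon}")
        norm[to_rna(codon)] += n
    out: dict[str, Optional[float]] = {}
    for family in code.families.values():
        total = sum(norm[c] for c in family)
        k = len(family)
        for c in family:
            out[c] = None if total == 0 else norm[c] * k / total
    return out


def aa_composition(codons: Iterable[str],
                   code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
    """Percent of residues per amino acid (three-letter keys, STOP excluded)."""
    residues = Counter(code.residue(c) for c in codons)
    residues.pop(STOP, None)
    residues.pop("X", None)
    total = sum(residues.values())
    if total == 0:
        raise ValueError("no non-STOP codons")
    return {_AA3[aa]: 100.0 * n / total for aa, n in sorted(residues.items())}


# ---------------------------------------------------------------------------
# Annotation-driven pipeline helpers


def gene_codons(genome: SequenceRecord, a: GenomeAnnotation,
                strand: Optional[str] = None) -> dict[str, list[str]]:
    """Codon lists for every PCG, keyed by gene name.

    Extracts each PCG's sense-strand sequence and applies
    :func:`extract_codons` with the annotated start/stop.  A gene whose
    remaining length is not a multiple of 3 (seen in some published
    organization tables) is truncated to the last complete codon with a
    warning instead of aborting the pipeline.
    """
    out: dict[str, list[str]] = {}
    for f in a.by_kind(PCG):
        if strand is not None and f.strand != strand:
            continue
        cds = genome.feature_seq(f)
        try:
            out[f.name] = extract_codons(cds, f.start_codon or "",
                                         f.stop_codon or "")
        except ValueError as exc:
            if "not divisible by 3" in str(exc):
                body = cds[4:] if len(f.start_codon or "") == 4 else cds
                if len(f.stop_codon or "") in (1, 2):
                    body = body[: -len(f.stop_codon)]
                usable = len(body) - len(body) % 3
                warnings.warn(
                    f"{f.name}: coding length {len(body)} not divisible by 3; "
                    f"truncating final partial codon")
                out[f.name] = [body[i:i + 3] for i in range(0, usable, 3)]
            else:
                raise ValueError(f"{f.name}: {exc}") from exc
    return out


def in_frame_cds(genome: SequenceRecord, a: GenomeAnnotation,
                 strand: Optional[str] = None) -> dict[str, str]:
    """In-frame sense-strand CDS per PCG (quadruplet start removed)."""
    return {name: "".join(codons)
            for name, codons in gene_codons(genome, a, strand).items()}


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts, RSCU and residue percentages of a codon pool."""

    counts: dict[str, int]
    rscu: dict[str, Optional[float]]
    aa_percent: dict[str, float]
    code: GeneticCode = INVERTEBRATE_MITO

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def codon_usage_table(genome: SequenceRecord, a: GenomeAnnotation,
                      strand: Optional[str] = None,
                      code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Pooled codon usage over the annotated PCGs (optionally one strand)."""
    pooled: Counter = Counter()
    for codons in gene_codons(genome, a, strand).values():
        pooled.update(to_rna(c) for c in codons)
    counts = dict(sorted(pooled.items()))
    return CodonUsageTable(counts=counts, rscu=rscu(counts, code),
                           aa_percent=aa_composition(Counter(counts).elements(),
                                                     code),
                           code=code)
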