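"""Synthetic circular mitogenome generator with a planted-truth record.

Generates genomes that carry, by construction, the structural and
statistical properties the analysis modules measure: the canonical 37-gene
dipteran gene order (23 genes on the J strand, 14 on N), protein-coding
genes with ATN (or one quadruplet ATCA) starts and complete TAA or
incomplete T/TA stops, tRNAs threaded onto sampled clover-leaf arm sizes
with Watson–Crick stems (optionally carrying planted U·U stem defects), two
rRNAs, and a control region with planted poly-T, (TA)n and G(A)nT elements.

Every planted quantity is stored in a *truth record*, so analysis outputs
can be validated exactly against what was generated (:func:`truth_check`).
Generation is fully deterministic given a seed.

Defaults emulate the published organization of a 16.1-kb anthomyiid
mitogenome: gene order, strands, anticodons, start/stop conventions and
per-class base composition (A+T ≈ 76–94% by class, ≈ 78.5% overall), with
seven U·U stem defects across the tRNAs and a control region carrying a
27-bp J-strand poly-T, a (TA)98 stretch on J, several G(A)nT elements on N
and a 37-bp N-strand poly-T.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .genome_model import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    GeneFeature,
    GenomeAnnotation,
    SequenceRecord,
    load_reference_annotation,
    revcomp,
)
from .codon_usage import INVERTEBRATE_MITO, translate
from .cr_motifs import GANT, POLY_T, TA_REPEAT, MotifHit
from .trna_structure import fold_trna

__all__ = [
    "GenerationError",
    "TemplateGene",
    "PlantedMotif",
    "GeneratorConfig",
    "default_template",
    "build_trna",
    "generate_mitogenome",
    "truth_check",
    "TruthReport",
]

_BASES = "ACGT"
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


class GenerationError(RuntimeError):
    """The generator could not satisfy its configuration."""


@dataclass(frozen=True)
class TemplateGene:
    """One slot of the gene-order template."""

    name: str
    kind: str
    strand: str
    size: int  # reference size in bp (tRNA sizes are resampled from arms)
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None


@dataclass(frozen=True)
class PlantedMotif:
    """A control-region element to plant: class, strand and repeat count."""

    motif: str
    strand: str
    n: int

    @property
    def length(self) -> int:
        if self.motif == POLY_T:
            return self.n
        if self.motif == TA_REPEAT:
            return 2 * self.n
        if self.motif == GANT:
            return self.n + 2
        raise ValueError(self.motif)


#: Per-kind sense-strand composition targets (%A+T fraction, AT skew, GC
#: skew), matching the class-level composition of the emulated genome.
DEFAULT_COMPOSITION = {
    PCG: (0.764, -0.15, 0.03),
    TRNA: (0.779, 0.02, 0.11),
    RRNA: (0.808, -0.01, 0.32),
    CONTROL_REGION: (0.937, -0.02, -0.30),
    "spacer": (0.785, 0.01, -0.17),
}

DEFAULT_PLANTED_MOTIFS = (
    PlantedMotif(POLY_T, "J", 27),
    PlantedMotif(TA_REPEAT, "J", 98),
    PlantedMotif(GANT, "N", 2),
    PlantedMotif(GANT, "N", 3),
    PlantedMotif(GANT, "N", 4),
    PlantedMotif(POLY_T, "N", 37),
)


def default_template() -> tuple[TemplateGene, ...]:
    """The canonical dipteran 37-gene + control-region order."""
    ref = load_reference_annotation()
    out = []
    for f in ref.features:
        out.append(TemplateGene(
            name=f.name, kind=f.kind, strand=f.strand,
            size=f.declared_size or (f.end - f.start + 1),
            anticodon=f.anticodon, start_codon=f.start_codon,
            stop_codon=f.stop_codon))
    return tuple(out)


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    template: tuple[TemplateGene, ...] = field(default_factory=default_template)
    target_length: int = 16141
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    planted_motifs: tuple[PlantedMotif, ...] = DEFAULT_PLANTED_MOTIFS
    planted_trna_defects: int = 7
    spacer_range: tuple[int, int] = (0, 8)
    min_cr_filler: int = 30


def _base_probs(at: float, at_sk: float, gc_sk: float) -> list[float]:
    """[pA, pC, pG, pT] from %A+T fraction and the two skews."""
    gc = 1.0 - at
    return [at * (1 + at_sk) / 2, gc * (1 - gc_sk) / 2,
            gc * (1 + gc_sk) / 2, at * (1 - at_sk) / 2]


def _sample_seq(rng: random.Random, n: int, probs: Sequence[float]) -> str:
    return "".join(rng.choices(_BASES, weights=probs, k=n))


def _conditional_at(probs: Sequence[float]) -> float:
    """Expected A+T fraction of base-wise codons conditioned on non-stop."""
    stops = {"TAA", "TAG"}
    idx = dict(zip(_BASES, probs))
    tot = at = 0.0
    for c1 in _BASES:
        for c2 in _BASES:
            for c3 in _BASES:
                if c1 + c2 + c3 in stops:
                    continue
                w = idx[c1] * idx[c2] * idx[c3]
                tot += w
                at += w * sum(b in "AT" for b in (c1, c2, c3)) / 3
    return at / tot


import functools


@functools.lru_cache(maxsize=None)
def _pcg_probs(at: float, at_sk: float, gc_sk: float) -> list[float]:
    """Base weights whose *stop-rejected* codon distribution hits ``at``.

    Rejecting the AT-rich stops TAA/TAG depresses realized A+T below the
    sampling weights; bisection on the weight-level A+T target removes the
    bias.
    """
    lo, hi = at, min(at + 0.05, 0.999)
    for _ in range(40):
        mid = (lo + hi) / 2
        if _conditional_at(_base_probs(mid, at_sk, gc_sk)) < at:
            lo = mid
        else:
            hi = mid
    return _base_probs((lo + hi) / 2, at_sk, gc_sk)


# ---------------------------------------------------------------------------
# Per-kind builders


def _build_pcg(rng: random.Random, g: TemplateGene, probs) -> tuple[str, str]:
    """Sense-strand CDS honouring the template's start/stop convention.

    Returns (cds, residues).  Interior codons are sampled base-wise at the
    target composition, rejecting in-frame stop codons.
    """
    start = (g.start_codon or "ATT").upper()
    stop = (g.stop_codon or "TAA").upper()
    stop_trim = len(stop) if len(stop) < 3 else 0
    body_len = g.size - len(start) - (3 if stop_trim == 0 else stop_trim)
    n_codons = body_len // 3  # partial codon in odd-sized templates is dropped
    codons = [start] if len(start) == 3 else []
    code = INVERTEBRATE_MITO.table
    while len(codons) < n_codons + (1 if len(start) == 3 else 0):
        c = _sample_seq(rng, 3, probs)
        if code[c.replace("T", "U")] == "*":
            continue
        codons.append(c)
    if len(start) == 4:
        cds = start + "".join(codons)
    else:
        cds = "".join(codons)
    residues = translate(codons)
    if stop_trim:
        cds += stop[:stop_trim]
    else:
        cds += "TAA"
        residues += "*"
    return cds, residues


def build_trna(rng: random.Random, anticodon: str, has_dhu: bool,
                n_defects: int, probs) -> tuple[str, tuple[int, int],
                                                tuple[int, int, int, int],
                                                list[tuple[int, int]]]:
    """One tRNA with Watson–Crick stems and ``n_defects`` planted U·U pairs.

    Returns (seq, anticodon span, (acc, dhu, ac, tpc) stem sizes, defect
    appositions in gene-local coordinates).  The construction is verified by
    refolding; if the fold does not recover the planted structure exactly the
    sequence is resampled (bounded retries), so truth records are exact.
    """
    anticodon = anticodon.upper().replace("U", "T")
    for _attempt in range(80):
        d = rng.choice((3, 4)) if has_dhu else 0
        dl = rng.randint(4, 8) if d else 0
        conn = rng.randint(4, 8) if not d else 0
        s1, s2 = (2, 1) if d else (conn, 0)
        ac = rng.choice((4, 5))
        t = rng.choice((3, 4, 5))
        tl = rng.randint(4, 8)
        var = rng.randint(3, 6)
        tail = rng.randint(1, 3)
        L = 7 + s1 + (2 * d + dl) + s2 + 2 * ac + 7 + var + 2 * t + tl + 7 + tail
        if not (55 <= L <= 80):
            continue
        seq = list(_sample_seq(rng, L, probs))
        p = 7 + s1 + 2 * d + dl + s2 + ac + 3  # anticodon start (1-based)
        seq[p - 1:p + 2] = list(anticodon)
        apps: list[tuple[int, int]] = []
        for k in range(1, 8):
            apps.append((k, L - tail + 1 - k))
        if d:
            u0 = 7 + s1
            for k in range(1, d + 1):
                apps.append((u0 + k, u0 + 2 * d + dl + 1 - k))
        for k in range(1, ac + 1):
            apps.append((p - 3 - ac + k, p + 5 + ac - k))
        w = p + 4 + ac + var
        for k in range(1, t + 1):
            apps.append((w + k, w + 2 * t + tl + 1 - k))
        for i, j in apps:  # thread complementary stems (WC only)
            b = rng.choices(_BASES, weights=probs)[0]
            seq[i - 1], seq[j - 1] = b, _WC[b]
        defects = sorted(rng.sample(apps, n_defects)) if n_defects else []
        for i, j in defects:
            seq[i - 1] = seq[j - 1] = "T"
        s = "".join(seq)
        leaf = fold_trna(s, (p, p + 2))
        if (leaf.arm_sizes == (7, d, ac, t)
                and len(leaf.mismatches) == n_defects
                and sorted((m.pos5, m.pos3) for m in leaf.mismatches) == defects
                and all(m.pair_type == "U-U" for m in leaf.mismatches)):
            return s, (p, p + 2), (7, d, ac, t), defects
    raise GenerationError(
        f"could not realize a verifiable tRNA (anticodon {anticodon}, "
        f"{n_defects} defects)")


def _build_control_region(rng: random.Random, length: int,
                          motifs: Sequence[PlantedMotif], probs,
                          min_filler: int) -> tuple[str, list[dict]]:
    """J-strand CR sequence with planted, C-guarded motif blocks.

    Each planted block is ``C + motif + C``; the C guards break poly-T runs,
    TA periodicity and G(A)nT spans, so planted hits are maximal and carry
    exactly the planted repeat count.  Returns (seq, planted records with
    CR-local 1-based coordinates).
    """
    blocks = []
    for m in motifs:
        if m.motif == POLY_T:
            core = "T" * m.n
        elif m.motif == TA_REPEAT:
            core = "TA" * m.n
        elif m.motif == GANT:
            core = "G" + "A" * m.n + "T"
        else:
            raise GenerationError(f"unknown motif class {m.motif}")
        if m.strand == "N":
            core = revcomp(core)
        blocks.append((m, "C" + core + "C"))
    planted_total = sum(len(b) for _, b in blocks)
    n_gaps = len(blocks) + 1
    if planted_total + n_gaps * min_filler > length:
        raise GenerationError(
            f"infeasible config: planted motifs ({planted_total} bp + filler) "
            f"exceed control-region length {length}")
    free = length - planted_total
    # gap lengths by stick-breaking with the minimum enforced
    extra = free - n_gaps * min_filler
    weights = [rng.random() for _ in range(n_gaps)]
    wsum = sum(weights)
    gaps = [min_filler + int(extra * w / wsum) for w in weights]
    gaps[-1] += free - sum(gaps)
    seq_parts: list[str] = []
    planted: list[dict] = []
    pos = 0
    for (m, block), gap in zip(blocks, gaps):
        seq_parts.append(_sample_seq(rng, gap, probs))
        pos += gap
        start = pos + 2  # skip the leading C guard
        planted.append({"motif": m.motif, "strand": m.strand, "n": m.n,
                        "start": start, "end": start + m.length - 1})
        seq_parts.append(block)
        pos += len(block)
    seq_parts.append(_sample_seq(rng, gaps[-1], probs))
    seq = "".join(seq_parts)
    assert len(seq) == length
    return seq, planted


# ---------------------------------------------------------------------------
# Whole-genome assembly


def generate_mitogenome(cfg: Optional[GeneratorConfig] = None,
                        seed: int = 0
                        ) -> tuple[SequenceRecord, GenomeAnnotation, dict]:
    """Generate one circular mitogenome, its annotation, and a truth record.

    The realized genome length equals ``cfg.target_length`` exactly: the
    control region absorbs the slack left by the fixed-size genes, sampled
    tRNAs and sampled intergenic spacers.  Same config + same seed gives
    byte-identical output.
    """
    cfg = cfg or GeneratorConfig()
    rng = random.Random(seed)
    genome_id = f"synthetic-mitogenome-seed{seed}"

    trna_slots = [g for g in cfg.template if g.kind == TRNA]
    defect_slots = rng.sample([g.name for g in trna_slots],
                              min(cfg.planted_trna_defects, len(trna_slots)))
    extra = cfg.planted_trna_defects - len(defect_slots)
    defects_per: dict[str, int] = {name: 1 for name in defect_slots}
    for _ in range(extra):  # more defects than tRNAs: pile on random slots
        defects_per[rng.choice(defect_slots)] += 1

    # Build every feature's sense-strand sequence (CR deferred: its length
    # absorbs the slack so the realized genome hits target_length).
    built: list[dict] = []
    for g in cfg.template:
        probs = _base_probs(*cfg.composition[g.kind])
        if g.kind == PCG:
            cds, residues = _build_pcg(rng, g, _pcg_probs(*cfg.composition[g.kind]))
            built.append({"g": g, "seq": cds, "residues": residues})
        elif g.kind == TRNA:
            has_dhu = "ser(agn)" not in g.name.lower()
            seq, span, arms, defects = build_trna(
                rng, g.anticodon or "CAT", has_dhu,
                defects_per.get(g.name, 0), probs)
            built.append({"g": g, "seq": seq, "ac_span": span,
                          "arms": arms, "defects": defects})
        elif g.kind == RRNA:
            built.append({"g": g, "seq": _sample_seq(rng, g.size, probs)})
        elif g.kind == CONTROL_REGION:
            built.append({"g": g, "seq": None})
        else:
            raise GenerationError(f"unknown kind {g.kind}")
    spacers = [rng.randint(*cfg.spacer_range) for _ in range(len(built) - 1)]
    fixed = sum(len(b["seq"]) for b in built if b["seq"] is not None)
    cr_len = cfg.target_length - fixed - sum(spacers)
    cr_slot = next(b for b in built if b["g"].kind == CONTROL_REGION)
    if cr_len < 1:
        raise GenerationError("infeasible config: no room for control region")
    cr_probs = _base_probs(*cfg.composition[CONTROL_REGION])
    cr_seq, cr_planted = _build_control_region(
        rng, cr_len, cfg.planted_motifs, cr_probs, cfg.min_cr_filler)
    cr_slot["seq"] = cr_seq

    # Assemble the J strand and the annotation.
    spacer_probs = _base_probs(*cfg.composition["spacer"])
    parts: list[str] = []
    feats: list[GeneFeature] = []
    truth_feats: list[dict] = []
    pos = 1
    for i, b in enumerate(built):
        g = b["g"]
        sense = b["seq"]
        j_piece = revcomp(sense) if g.strand == "N" else sense
        start, end = pos, pos + len(sense) - 1
        ac_span = None
        if g.kind == TRNA:
            p, q = b["ac_span"]
            ac_span = ((start + p - 1, start + q - 1) if g.strand == "J"
                       else (end - q + 1, end - p + 1))
        feats.append(GeneFeature(
            name=g.name, kind=g.kind, strand=g.strand, start=start, end=end,
            anticodon_span=ac_span,
            anticodon=g.anticodon if g.kind == TRNA else None,
            start_codon=g.start_codon if g.kind == PCG else None,
            stop_codon=g.stop_codon if g.kind == PCG else None,
            declared_size=len(sense)))
        tf = {"name": g.name, "kind": g.kind, "strand": g.strand,
              "start": start, "end": end, "length": len(sense)}
        if g.kind == PCG:
            tf["residues"] = b["residues"]
        if g.kind == TRNA:
            tf["arms"] = list(b["arms"])
            tf["defects"] = [list(x) for x in b["defects"]]
        if g.kind == CONTROL_REGION:
            tf["planted_motifs"] = [
                {**m, "start": start + m["start"] - 1,
                 "end": start + m["end"] - 1} for m in cr_planted]
        truth_feats.append(tf)
        parts.append(j_piece)
        pos = end + 1
        if i < len(built) - 1 and spacers[i]:
            parts.append(_sample_seq(rng, spacers[i], spacer_probs))
            pos += spacers[i]
    genome = SequenceRecord(id=genome_id, seq="".join(parts))
    annotation = GenomeAnnotation(features=tuple(feats),
                                  genome_length=len(genome.seq))
    assert len(genome.seq) == cfg.target_length
    truth = {
        "id": genome_id,
        "seed": seed,
        "genome_length": len(genome.seq),
        "features": truth_feats,
        "planted_motifs": [m for tf in truth_feats
                           for m in tf.get("planted_motifs", [])],
        "planted_defect_total": cfg.planted_trna_defects,
        "planted_defect_type": "U-U",
        "targets": {"whole_genome_at_fraction": _whole_at_target(cfg)},
    }
    return genome, annotation, truth


def _whole_at_target(cfg: GeneratorConfig) -> float:
    """Length-weighted A+T target implied by the per-kind targets."""
    total = w = 0.0
    for g in cfg.template:
        at = cfg.composition[g.kind][0]
        total += at * g.size
        w += g.size
    return total / w


# ---------------------------------------------------------------------------
# Planted-truth validation


@dataclass(frozen=True)
class TruthReport:
    """Outcome of comparing analysis outputs against a truth record."""

    checked: int
    discrepancies: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.discrepancies


def truth_check(truth: dict, *, annotation: Optional[GenomeAnnotation] = None,
                motifs: Optional[Sequence[MotifHit]] = None,
                census: Optional[Sequence] = None,
                genome_id: Optional[str] = None) -> TruthReport:
    """Compare recovered analysis outputs against the planted truth.

    Pass whichever outputs were produced: ``annotation`` (geometry check),
    ``motifs`` (control-region scan; every planted motif must be present
    with exact coordinates, strand and repeat count), ``census``
    (gene-attributed tRNA mismatch list; must equal the planted defects
    exactly, all of the planted pair type).  Discrete quantities must match
    exactly.  Raises ``ValueError`` on a genome-identifier mismatch.
    """
    if genome_id is not None and genome_id != truth["id"]:
        raise ValueError(
            f"genome id mismatch: outputs from {genome_id!r}, "
            f"truth from {truth['id']!r}")
    checked = 0
    problems: list[str] = []
    if annotation is not None:
        by_name = {f.name: f for f in annotation.features}
        for tf in truth["features"]:
            checked += 1
            f = by_name.get(tf["name"])
            if f is None:
                problems.append(f"feature {tf['name']} missing")
                continue
            got = (f.start, f.end, f.strand, f.kind)
            want = (tf["start"], tf["end"], tf["strand"], tf["kind"])
            if got != want:
                problems.append(f"{tf['name']}: {got} != planted {want}")
    if motifs is not None:
        found = {(h.motif, h.strand, h.start, h.end, h.n) for h in motifs}
        for m in truth["planted_motifs"]:
            checked += 1
            key = (m["motif"], m["strand"], m["start"], m["end"], m["n"])
            if key not in found:
                problems.append(f"planted motif not recovered: {key}")
    if census is not None:
        checked += 1
        want_type = truth["planted_defect_type"]
        if len(census) != truth["planted_defect_total"]:
            problems.append(
                f"defect census size {len(census)} != planted "
                f"{truth['planted_defect_total']}")
        bad = [(g, m) for g, m in census if m.pair_type != want_type]
        if bad:
            problems.append(f"non-{want_type} mismatches recovered: {bad}")
        planted = {(tf["name"], tuple(d)) for tf in truth["features"]
                   for d in tf.get("defects", [])}
        got = {(g, (m.pos5, m.pos3)) for g, m in census}
        if planted != got:
            problems.append(
                f"defect coordinates differ: planted {sorted(planted)} vs "
                f"recovered {sorted(got)}")
    return TruthReport(checked=checked, discrepancies=tuple(problems))
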