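"""Template-constrained tRNA clover-leaf folding and mismatch census.

Mitochondrial tRNAs (63–72 bp here) fold into the canonical clover-leaf:
acceptor (amino-acid) stem of 7 pairs, DHU arm (3–4 pairs, absent in
mitochondrial tRNA-Ser(AGN)), anticodon arm (4–5 pairs) whose 7-base loop
carries the anticodon at its centre, a variable region, and a TΨC arm (3–5
pairs).  Rather than thermodynamic folding, this module enumerates every arm
size assignment consistent with those bounds, *anchored at the annotated
anticodon*, and keeps the assignment that maximizes admissible stem pairs —
a deterministic, annotation-driven reconstruction.

Admissible pairs are Watson–Crick plus the G·U wobble; any other stem
apposition (e.g. the U·U appositions typical of insect mitochondrial tRNAs)
is recorded as a mismatch with its coordinates and bases.

Layout enumerated (5'→3', sizes in nt)::

    acceptor5(7) s1 [DHU5(d) dloop DHU3(d)] s2 AC5(ac) acloop(7) AC3(ac)
    variable TPC5(t) tloop TPC3(t) acceptor3(7) tail

with d ∈ {0, 3, 4} (0 = arm absent, then s1+s2 collapse into one connector),
ac ∈ {4, 5}, t ∈ {3, 4, 5}, loops 3–9 (anticodon loop fixed at 7), s1 1–3,
s2 0–2, connector 1–12, variable 0–23, tail 0–4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .genome_model import (
    TRNA,
    GeneFeature,
    GenomeAnnotation,
    SequenceRecord,
    feature_length,
)

__all__ = [
    "ADMISSIBLE_PAIRS",
    "CloverLeaf",
    "Mismatch",
    "FoldError",
    "fold_trna",
    "mismatch_census",
    "to_dot_bracket",
    "parse_dot_bracket",
]

#: Admissible stem pairs: Watson–Crick + G·U wobble (DNA alphabet; U≡T).
ADMISSIBLE_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

MIN_LEN, MAX_LEN = 55, 80
_D_SIZES = (4, 3, 0)
_AC_SIZES = (5, 4)
_T_SIZES = (5, 4, 3)
_LOOP_RANGE = range(3, 10)
_S1_RANGE = range(1, 4)
_S2_RANGE = range(0, 3)
_CONNECTOR_RANGE = range(1, 13)
_VAR_RANGE = range(0, 24)
_TAIL_RANGE = range(0, 5)


class FoldError(ValueError):
    """No arm-size assignment satisfies the clover-leaf bounds."""


@dataclass(frozen=True)
class Mismatch:
    """A stem apposition that is not an admissible pair (1-based coords)."""

    pos5: int
    pos3: int
    base5: str
    base3: str

    @property
    def pair_type(self) -> str:
        """Canonical RNA-alphabet label, e.g. ``"U-U"``."""
        a, b = sorted((self.base5.replace("T", "U"),
                       self.base3.replace("T", "U")))
        return f"{a}-{b}"


@dataclass(frozen=True)
class CloverLeaf:
    """One folded tRNA: arm decomposition, pair list and mismatches.

    All coordinates are 1-based within the tRNA's sense-strand sequence.
    ``pairs`` holds the admissible stem pairs only; mismatched stem
    appositions are in ``mismatches``.  ``dhu_stem == 0`` marks a
    DHU-arm-less structure (tRNA-Ser(AGN) type).
    """

    seq: str
    anticodon_span: tuple[int, int]
    acceptor_stem: int
    dhu_stem: int
    dhu_loop: int
    anticodon_stem: int
    tpc_stem: int
    tpc_loop: int
    spacer1: int
    spacer2: int
    variable: int
    tail: int
    pairs: tuple[tuple[int, int], ...]
    mismatches: tuple[Mismatch, ...]

    @property
    def has_dhu_arm(self) -> bool:
        return self.dhu_stem > 0

    @property
    def paired(self) -> int:
        return len(self.pairs)

    @property
    def stem_positions(self) -> int:
        return (self.acceptor_stem + self.dhu_stem + self.anticodon_stem
                + self.tpc_stem)

    @property
    def anticodon(self) -> str:
        p, q = self.anticodon_span
        return self.seq[p - 1:q]

    @property
    def arm_sizes(self) -> tuple[int, int, int, int]:
        """(acceptor, DHU, anticodon, TΨC) stem sizes."""
        return (self.acceptor_stem, self.dhu_stem, self.anticodon_stem,
                self.tpc_stem)


def _appositions(L: int, p: int, params: tuple):
    """Yield (5', 3') stem appositions of one arm assignment, stem by stem."""
    d, dl, s1, s2, ac, t, tl, var, tail = params
    for k in range(1, 8):  # acceptor
        yield k, L - tail + 1 - k
    if d:
        u0 = 7 + s1
        for k in range(1, d + 1):
            yield u0 + k, u0 + 2 * d + dl + 1 - k
    for k in range(1, ac + 1):  # anticodon arm
        yield p - 3 - ac + k, p + 5 + ac - k
    w = p + 4 + ac + var  # last position before the TΨC 5' stem
    for k in range(1, t + 1):
        yield w + k, w + 2 * t + tl + 1 - k


def _candidates(L: int, p: int):
    """Enumerate feasible (d, dl, s1, s2, ac, t, tl, var, tail) tuples.

    Enumeration order is fixed (documented in the module docstring's
    parameter order) so tie-breaking by first occurrence is deterministic.
    """
    U = p - 3  # length upstream of the anticodon 5' stem start, minus stem
    for ac in _AC_SIZES:
        up = U - ac  # bases before the anticodon 5' stem
        if up < 7:
            continue
        down = L - (p + 4 + ac)  # bases after the anticodon 3' stem
        ups = []
        for d in _D_SIZES:
            if d == 0:
                c = up - 7
                if c in _CONNECTOR_RANGE:
                    ups.append((0, 0, c, 0))
            else:
                for s1 in _S1_RANGE:
                    for s2 in _S2_RANGE:
                        dl = up - 7 - s1 - 2 * d - s2
                        if dl in _LOOP_RANGE:
                            ups.append((d, dl, s1, s2))
        if not ups:
            continue
        downs = []
        for t in _T_SIZES:
            for tl in _LOOP_RANGE:
                for tail in _TAIL_RANGE:
                    var = down - 2 * t - tl - 7 - tail
                    if var in _VAR_RANGE:
                        downs.append((t, tl, var, tail))
        for d, dl, s1, s2 in ups:
            for t, tl, var, tail in downs:
                yield d, dl, s1, s2, ac, t, tl, var, tail


def fold_trna(seq: str, anticodon_span: tuple[int, int]) -> CloverLeaf:
    """Fold a sense-strand tRNA sequence anchored at its anticodon.

    ``anticodon_span`` is the 1-based inclusive position pair of the 3-nt
    anticodon *within* ``seq``.  Among all arm assignments satisfying the
    clover-leaf bounds, returns the one maximizing admissible pairs, ties
    broken by fewer mismatched stem positions, then larger DHU arm, then
    enumeration order.  Raises :class:`FoldError` if none is feasible.
    """
    seq = seq.upper().replace("U", "T")
    L = len(seq)
    if not (MIN_LEN <= L <= MAX_LEN):
        raise FoldError(f"length {L} outside {MIN_LEN}-{MAX_LEN}")
    p, q = anticodon_span
    if q - p != 2 or not (1 <= p and q <= L):
        raise FoldError(f"anticodon span {anticodon_span} invalid for length {L}")

    admissible = ADMISSIBLE_PAIRS
    best_key: Optional[tuple[int, int, int]] = None
    best_params = None
    for params in _candidates(L, p):
        paired = 0
        for i, j in _appositions(L, p, params):
            if (seq[i - 1], seq[j - 1]) in admissible:
                paired += 1
        d, ac, t = params[0], params[4], params[5]
        key = (paired, paired - (7 + d + ac + t), d)
        if best_key is None or key > best_key:
            best_key, best_params = key, params
    if best_params is None:
        raise FoldError("no clover-leaf: no arm assignment satisfies bounds")
    d, dl, s1, s2, ac, t, tl, var, tail = best_params
    pairs: list[tuple[int, int]] = []
    mismatches: list[Mismatch] = []
    for i, j in _appositions(L, p, best_params):
        bi, bj = seq[i - 1], seq[j - 1]
        if (bi, bj) in admissible:
            pairs.append((i, j))
        else:
            mismatches.append(Mismatch(i, j, bi, bj))
    return CloverLeaf(
        seq=seq, anticodon_span=(p, q), acceptor_stem=7, dhu_stem=d,
        dhu_loop=dl, anticodon_stem=ac, tpc_stem=t, tpc_loop=tl, spacer1=s1,
        spacer2=s2, variable=var, tail=tail, pairs=tuple(pairs),
        mismatches=tuple(mismatches))


def _anticodon_in_gene(f: GeneFeature, genome_length: int) -> tuple[int, int]:
    """Map a J-strand anticodon span into 1-based sense-strand gene coords."""
    a, b = f.anticodon_span  # type: ignore[misc]
    if f.strand == "J":
        return ((a - f.start) % genome_length + 1,
                (b - f.start) % genome_length + 1)
    return ((f.end - b) % genome_length + 1,
            (f.end - a) % genome_length + 1)


def fold_annotated(genome: SequenceRecord, a: GenomeAnnotation,
                   f: GeneFeature) -> CloverLeaf:
    """Fold one annotated tRNA feature (requires an anticodon span)."""
    if f.anticodon_span is None:
        raise FoldError(f"{f.name}: no anticodon annotation")
    seq = genome.feature_seq(f)
    return fold_trna(seq, _anticodon_in_gene(f, a.genome_length))


def mismatch_census(a: GenomeAnnotation, genome: SequenceRecord
                    ) -> tuple[list[tuple[str, Mismatch]], dict[str, int]]:
    """Fold all annotated tRNAs and pool their stem mismatches.

    Returns (census, by_type): ``census`` is a gene-attributed mismatch list
    in annotation order; ``by_type`` counts mismatches per canonical pair
    label (e.g. ``{"U-U": 7}``).  tRNAs without an anticodon span are
    skipped with a warning.
    """
    import warnings
    from collections import Counter

    census: list[tuple[str, Mismatch]] = []
    by_type: Counter = Counter()
    for f in a.by_kind(TRNA):
        if f.anticodon_span is None:
            warnings.warn(f"{f.name}: missing anticodon annotation; skipped")
            continue
        leaf = fold_annotated(genome, a, f)
        for m in leaf.mismatches:
            census.append((f.name, m))
            by_type[m.pair_type] += 1
    return census, dict(by_type)


def to_dot_bracket(c: CloverLeaf) -> str:
    """Dot-bracket string of the admissible pair set (mismatches are dots)."""
    chars = ["."] * len(c.seq)
    for i, j in c.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def parse_dot_bracket(s: str) -> frozenset[tuple[int, int]]:
    """Pair set (1-based) of a dot-bracket string; raises on imbalance."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(s, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at {pos}")
            pairs.add((stack.pop(), pos))
    if stack:
        raise ValueError(f"unclosed '(' at {stack[-1]}")
    return frozenset(pairs)
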