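# Methods

This note records the models, conventions and numerical choices behind
`mitoprofile`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate model and gene geometry

All I/O uses 1-based inclusive coordinates on the majority (J) strand of a
circular molecule; minority-strand (N) features are stored with J-strand
coordinates and a strand flag, and their analyses always read the
reverse-complemented *sense* sequence. A feature with `end < start` wraps
the origin; its length is `genome_length − start + 1 + end`.

The signed gap between consecutive annotated features is
`next.start − prev.end − 1` (positive = spacer, negative = overlap, 0 =
abutting), attributed to the *following* feature's row as organization
tables conventionally do. The last→first pair is computed circularly, with
the gap mapped to its smallest-magnitude representation around the origin —
adequate because adjacent annotated features are never half a genome apart.
The overlap census reports the recomputed count of negative gaps; where a
source table's prose and its own column arithmetic disagree, the recomputed
column arithmetic wins.

Geometry is validated against an independent position-wise coverage oracle:
on random annotations whose feature lengths (≥ 20 bp) exceed twice the
maximum overlap (8 bp), overlap regions of distinct pairs cannot stack, so
bases covered by zero features equal the spacer total and multiply-covered
bases equal the overlap total.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); both are scale-invariant, so
printed percentages and raw counts give identical values. U counts as T;
ambiguous bases are tallied separately and excluded from all numerators and
denominators. Pooled feature classes concatenate *sense-strand* sequences —
the only reading under which J- and N-strand gene classes can differ, which
is the point of reporting them separately. Whole-genome statistics use the
stored J strand. Nucleotides shared by overlapping features count once per
feature, so class totals may double-count a few dozen bases; no published
convention resolves this and the effect is below reporting precision.
Reporting precision is 1 decimal for percentages, 2 decimals for
table-style skews and 3 for comparative (scatter) skews, rounded half-up;
unrounded values are carried internally.

Codon-position composition requires in-frame sense-strand CDSs (quadruplet
starts already removed); a trailing incomplete codon is ignored, and
sequences shorter than one codon are skipped with a warning.

## Codon usage

Translation uses NCBI genetic code table 5 (invertebrate mitochondrial),
taken from Biopython's `CodonTable` — under it serine is an eight-codon
family (UCN + AGN) and only UAA/UAG terminate. Conventions, chosen once:

* a 4-nt quadruplet start (e.g. ATCA) is consumed whole and excluded from
  codon statistics — it is not a codon, and removing it leaves the CDS in
  frame; 3-nt starts are ordinary codons and are counted;
* declared incomplete stops (T, TA) are trimmed and not counted; complete
  stops are counted as members of the two-codon UAA/UAG family, which
  therefore carries RSCU values;
* a CDS whose remaining length is not divisible by 3 (this occurs in at
  least one published organization table) has its final partial codon
  truncated with a warning rather than aborting the pipeline.

RSCU(c) = count(c) × k / Σ family counts with k the family size; an unused
family's RSCU is reported missing, never 0. Amino-acid percentages exclude
STOP from the denominator.

## tRNA clover-leaf folding

Structures are *reconstructed*, not predicted: the annotation supplies the
anticodon, and the folder enumerates every arm-size assignment within
canonical mitochondrial bounds — acceptor stem 7 bp; DHU stem 0 (absent), 3
or 4 bp with loop 3–9; anticodon stem 4–5 bp with the 7-base loop centred on
the anticodon; TΨC stem 3–5 bp with loop 3–9; spacers 1–3 and 0–2 nt (a
single 1–12 nt connector when the DHU arm is absent); variable region 0–23
nt; 3' tail 0–4 nt. Admissible pairs are Watson–Crick plus the G·U wobble;
treating G·U as a mismatch would misclassify ubiquitous wobble pairs and
drown the U·U appositions the census is after. The returned structure
maximizes admissible pairs, with ties broken by fewer mismatched stem
positions, then larger DHU arm, then a frozen enumeration order — changing
that order is a breaking change. Enumeration is exhaustive within bounds
(a few thousand candidates per tRNA), so folding is deterministic and free
of thermodynamic parameters; it does not attempt de-novo tRNA detection or
minimum-free-energy folding.

Dot-bracket serialization writes brackets for admissible pairs only;
mismatched stem positions remain dots, so round-tripping reproduces the
pair set exactly and the output is always pseudoknot-free by construction.

## Control-region scanners

Poly-T runs, (TA)n repeats and G(A)nT elements are found as maximal matches
(regular-expression semantics) on both strand readings, with N-strand hits
mapped back into J-strand coordinates so all hits share one coordinate
system. (TA)n is phase-agnostic: a maximal alternating T/A run is reported
in the TA frame maximizing the unit count. Default thresholds — poly-T runs
≥ 10 bp, ≥ 5 TA units, ≥ 1 A in G(A)nT — are detection floors chosen to pass
biologically reported elements (runs of 27–37 bp, a 98-unit repeat) while
suppressing trivial dinucleotides; published descriptions report found
elements but never their detection thresholds, so these are explicit,
config-overridable parameters.

## Synthetic genomes and what the tests show

The generator emulates the study conditions of a 16.1-kb dipteran
mitogenome: the canonical 37-gene + control-region order with its strand
assignments, anticodons and start/stop conventions taken from the bundled
organization table; per-class sense-strand composition targets of 76.4%
(PCG), 77.9% (tRNA), 80.8% (rRNA) and 93.7% (control region) A+T with the
corresponding class skews, which yield ≈ 78.5% genome-wide; seven U·U stem
defects distributed over the tRNAs; and a control region carrying a 27-bp
J-strand poly-T, a (TA)₉₈ stretch, three G(A)nT elements on N and a 37-bp
N-strand poly-T, each flanked by single C guards so planted hits are
maximal with exactly the planted repeat count. The realized genome length
equals the configured target exactly (the control region absorbs slack);
intergenic spacers are sampled at 0–8 bp and gene overlaps are not
generated, since one sequence cannot simultaneously satisfy two planted
structural constraints.

Two sampling details matter for fidelity. PCG interiors are sampled
base-wise with in-frame stop codons rejected; because TAA/TAG are AT-rich,
naive rejection depresses realized A+T by ≈ 1 point, so the sampling
weights are pre-adjusted by bisection until the *stop-conditioned* codon
distribution hits the class target. Each tRNA is verified at generation
time by refolding: if the fold does not recover the planted arms and
defects exactly, the tRNA is resampled (bounded retries). Truth records are
therefore exact for any seed by construction — parameter-recovery tests
check that this contract holds, not that an unconstrained random sequence
folds uniquely.

Limitations of the emulation: bases are i.i.d. within a class, so there is
no codon-position bias (real third positions are more AT-rich than first
and second), no amino-acid preference structure, no sequence homology to
any real gene, and rRNA secondary structure is not modelled. Passing the
planted-truth tests demonstrates that the *measurement* pipeline is exact
on genomes satisfying its assumptions; it says nothing about annotation
quality or structure prediction on real sequences, which this package by
design takes as given.

## Problem sizes and determinism

The test suite and the acceptance script run desk-scale inputs (the 38-row
bundled table), 100–1000-iteration property checks, and a handful of 16-kb
synthetic genomes (≈ 1 s each to generate, ≈ 1 s to analyse); the
composition calibration check averages 20 seeds. All randomness flows
through explicit `random.Random(seed)` instances; hypothesis tests are
derandomized. Same seed, same bytes.
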