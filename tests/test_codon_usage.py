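"""Codon extraction conventions, table-5 translation, RSCU and residue use."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoprofile.codon_usage import (
    INVERTEBRATE_MITO,
    aa_composition,
    codon_usage_table,
    extract_codons,
    gene_codons,
    rscu,
    translate,
)

CODONS = [a + b + c for a in "ACGU" for b in "ACGU" for c in "ACGU"]


class TestGeneticCode:
    def test_clade_specific_assignments(self):
        """The invertebrate-mitochondrial reassignments relative to the
        standard code: AGA/AGG→Ser, UGA→Trp, AUA→Met."""
        code = INVERTEBRATE_MITO
        assert code.residue("AGA") == "S" and code.residue("AGG") == "S"
        assert code.residue("TGA") == "W"
        assert code.residue("ATA") == "M"
        assert code.residue("UAA") == "*" and code.residue("UAG") == "*"

    def test_family_structure(self):
        fams = INVERTEBRATE_MITO.families
        assert len(fams["S"]) == 8  # UCN + AGN
        assert len(fams["L"]) == 6
        assert len(fams["*"]) == 2  # UAA/UAG only
        assert sum(len(v) for v in fams.values()) == 64


class TestExtractCodons:
    def test_plain_gene(self):
        assert extract_codons("ATGTTTTAA", "ATG", "TAA") == ["ATG", "TTT", "TAA"]

    def test_quadruplet_start_consumed(self):
        cds = "ATCA" + "TTT" * 5 + "TAA"
        out = extract_codons(cds, "ATCA", "TAA")
        assert out == ["TTT"] * 5 + ["TAA"]

    def test_incomplete_stop_trimmed(self):
        assert extract_codons("ATGTTTT", "ATG", "T") == ["ATG", "TTT"]
        assert extract_codons("ATGTTTTA", "ATG", "TA") == ["ATG", "TTT"]

    def test_declared_start_must_be_prefix(self):
        with pytest.raises(ValueError, match="not a prefix"):
            extract_codons("ATGTTTTAA", "ATT", "TAA")

    def test_frame_error_reported(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            extract_codons("ATGTTTT", "ATG", "TAA")

    def test_generated_gene_lengths(self, synth):
        """Codon counts follow the organization-table sizes: a 1017-bp gene
        yields 339 codons with its stop; the quadruplet-start gene yields
        (size-4)/3."""
        genome, ann, _ = synth
        codons = gene_codons(genome, ann)
        from mitoprofile.genome_model import feature_length

        for f in ann.by_kind("PCG"):
            n = feature_length(f, ann.genome_length)
            expect = (n - 4) // 3 if len(f.start_codon or "") == 4 else (
                (n - len(f.stop_codon)) // 3 if len(f.stop_codon) < 3
                else n // 3)
            assert len(codons[f.name]) == expect, f.name
        nd2 = ann.get("ND2")
        assert len(codons["ND2"]) == feature_length(nd2, ann.genome_length) // 3


class TestTranslate:
    def test_examples(self):
        assert translate(["ATT", "TTA", "TAA"]) == "IL*"
        assert translate(["AGA", "TGA", "ATA"]) == "SWM"

    def test_ambiguous_codon_is_placeholder(self):
        assert translate(["ANN"]) == "X"

    def test_round_trip_with_generator_truth(self, synth):
        """Translating extracted codons recovers every planted residue
        sequence exactly."""
        genome, ann, truth = synth
        codons = gene_codons(genome, ann)
        planted = {f["name"]: f["residues"] for f in truth["features"]
                   if "residues" in f}
        for name, residues in planted.items():
            assert translate(codons[name]) == residues, name


class TestRSCU:
    def test_uniform_family_is_all_ones(self):
        counts = {c: 7 for c in INVERTEBRATE_MITO.families["L"]}
        out = rscu(counts)
        for c in INVERTEBRATE_MITO.families["L"]:
            assert out[c] == pytest.approx(1.0)

    def test_hand_evaluated_leucine_family(self):
        counts = {"UUA": 8, "UUG": 2, "CUU": 2}
        out = rscu(counts)
        assert out["UUA"] == pytest.approx(8 * 6 / 12) == 4.0

    def test_unused_family_is_missing_not_zero(self):
        out = rscu({"UUA": 3})
        assert out["GGA"] is None

    def test_family_sums_equal_family_size(self, synth):
        genome, ann, _ = synth
        tab = codon_usage_table(genome, ann)
        for aa, family in INVERTEBRATE_MITO.families.items():
            vals = [tab.rscu[c] for c in family]
            if all(v is None for v in vals):
                continue
            assert sum(vals) == pytest.approx(len(family))

    @given(st.dictionaries(st.sampled_from(CODONS), st.integers(0, 500),
                           min_size=1), st.integers(1, 9))
    @settings(derandomize=True, max_examples=60)
    def test_scaling_invariance(self, counts, k):
        base = rscu(counts)
        scaled = rscu({c: n * k for c, n in counts.items()})
        for c in base:
            if base[c] is None:
                assert scaled[c] is None
            else:
                assert scaled[c] == pytest.approx(base[c])

    @given(st.dictionaries(st.sampled_from(CODONS), st.integers(0, 500),
                           min_size=1))
    @settings(derandomize=True, max_examples=60)
    def test_family_sum_invariant(self, counts):
        out = rscu(counts)
        for family in INVERTEBRATE_MITO.families.values():
            vals = [out[c] for c in family]
            if any(v is not None for v in vals):
                assert sum(vals) == pytest.approx(len(family))


class TestAAComposition:
    def test_single_codon(self):
        assert aa_composition(["UUA"]) == {"Leu": 100.0}

    def test_stop_excluded_from_denominator(self):
        out = aa_composition(["UUA", "UUA", "UAA"])
        assert out == {"Leu": 100.0}

    def test_zero_informative_codons_error(self):
        with pytest.raises(ValueError):
            aa_composition(["UAA"])

    def test_random_multiset_matches_direct_tally(self):
        rng = random.Random(4)
        codons = rng.choices(CODONS, k=2000)
        out = aa_composition(codons)
        tally = Counter(INVERTEBRATE_MITO.residue(c) for c in codons)
        tally.pop("*", None)
        total = sum(tally.values())
        assert out["Leu"] == pytest.approx(100 * tally["L"] / total)
        assert sum(out.values()) == pytest.approx(100)

    def test_percentages_sum_to_100_in_pipeline(self, synth):
        genome, ann, _ = synth
        tab = codon_usage_table(genome, ann)
        assert sum(tab.aa_percent.values()) == pytest.approx(100, abs=0.2)
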