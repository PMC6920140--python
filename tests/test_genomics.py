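"""Translation, reverse translation, coding-match search, conservation."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from peptidogenomics.genomics import (
    NucSeq,
    conservation,
    find_coding_matches,
    reverse_translate_pattern,
    translate,
)
from peptidogenomics.synthetic import SimulationConfig, simulate_genome_with_gene

from conftest import HEPCIDIN

# the antisense 23-mer whose reverse complement encodes DTHFPIC
ANTISENSE_23MER = "ATGCAGATGGGGAAGTGGGTGTC"

_PEPTIDE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class TestTranslate:
    def test_atg_is_methionine(self):
        assert translate(NucSeq(id="x", sequence="ATG")) == "M"

    def test_antisense_23mer_reads_dthfpic(self):
        nuc = NucSeq(id="wolf-scaffold", sequence=ANTISENSE_23MER)
        assert translate(nuc, frame=0, strand="-").startswith("DTHFPIC")

    def test_stop_codon_rendered_as_star(self):
        assert translate(NucSeq(id="x", sequence="TAAATG")) == "*M"

    def test_ambiguous_codon_rendered_as_x(self):
        assert translate(NucSeq(id="x", sequence="ANTATG")) == "XM"

    def test_trailing_partial_codon_dropped(self):
        assert translate(NucSeq(id="x", sequence="ATGCC")) == "M"

    def test_invalid_frame_or_strand(self):
        nuc = NucSeq(id="x", sequence="ATG")
        with pytest.raises(ValueError):
            translate(nuc, frame=3)
        with pytest.raises(ValueError):
            translate(nuc, strand="*")

    def test_minus_strand_equals_plus_of_reverse_complement(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        nuc = NucSeq(id="x", sequence=seq)
        rc = NucSeq(id="rc", sequence=str(Seq(seq).reverse_complement()))
        for frame in (0, 1, 2):
            assert translate(nuc, frame, "-") == translate(rc, frame, "+")


class TestNucSeq:
    def test_lowercase_normalised(self):
        assert NucSeq(id="x", sequence="acgt").sequence == "ACGT"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            NucSeq(id="x", sequence="ACGU")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            NucSeq(id="x", sequence="")


class TestReverseTranslatePattern:
    def test_single_codon_residues(self):
        assert re.fullmatch(reverse_translate_pattern("M"), "ATG")
        assert re.fullmatch(reverse_translate_pattern("W"), "TGG")
        assert not re.fullmatch(reverse_translate_pattern("M"), "ATA")

    def test_dthfpic_matches_printed_coding_sequence(self):
        pattern = reverse_translate_pattern("DTHFPIC")
        assert re.fullmatch(pattern, "GACACCCACTTCCCCATCTGC")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.text(alphabet=_PEPTIDE_ALPHABET, min_size=1, max_size=8),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_matches_exactly_the_coding_sequences(self, peptide, seed):
        """Any sampled codon realisation matches; what matches translates
        back to the peptide."""
        from peptidogenomics.genomics import _codons_for

        rng = np.random.default_rng(seed)
        dna = "".join(
            _codons_for(aa)[rng.integers(len(_codons_for(aa)))]
            for aa in peptide
        )
        pattern = reverse_translate_pattern(peptide)
        assert re.fullmatch(pattern, dna)
        assert translate(NucSeq(id="x", sequence=dna)) == peptide


class TestFindCodingMatches:
    def test_antisense_23mer_found_on_minus_strand(self):
        rng = np.random.default_rng(0)
        flank = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        seq = flank(200) + ANTISENSE_23MER + flank(200)
        hits = find_coding_matches("DTHFPIC", NucSeq(id="x", sequence=seq))
        assert len(hits) == 1
        assert hits[0].strand == "-"
        start, end = hits[0].exons[0]
        assert seq[start:end] in ANTISENSE_23MER

    def test_contiguous_plant_found_with_exact_interval(self):
        nuc, truth = simulate_genome_with_gene(
            SimulationConfig(seed=2, genome_length=20_000, exon_plan=(25,))
        )
        hits = find_coding_matches(HEPCIDIN, nuc, max_exons=1)
        assert any(
            h.strand == truth.strand and h.exons == truth.exons for h in hits
        )

    def test_three_exon_plant_recovered(self):
        nuc, truth = simulate_genome_with_gene(
            SimulationConfig(seed=3, genome_length=50_000)
        )
        hits = find_coding_matches(HEPCIDIN, nuc, max_exons=3)
        assert any(
            h.strand == truth.strand and h.exons == truth.exons for h in hits
        )

    def test_absent_peptide_gives_empty_list(self):
        nuc, _ = simulate_genome_with_gene(
            SimulationConfig(seed=4, genome_length=20_000, exon_plan=())
        )
        assert find_coding_matches(HEPCIDIN, nuc) == []

    def test_short_query_rejected(self):
        nuc = NucSeq(id="x", sequence="ACGTACGTACGT")
        with pytest.raises(ValueError):
            find_coding_matches("MW", nuc)

    def test_false_positive_rate_small_on_random_dna(self):
        """A >=7-residue query essentially never matches random DNA."""
        for seed in range(5):
            nuc, _ = simulate_genome_with_gene(
                SimulationConfig(
                    seed=100 + seed, genome_length=50_000, exon_plan=()
                )
            )
            assert find_coding_matches("DTHFPIC", nuc, max_exons=1) == []


class TestConservation:
    def test_identical_sequences(self):
        report = conservation({"a": HEPCIDIN, "b": HEPCIDIN})
        assert report.identity_matrix.loc["a", "b"] == 100.0
        assert report.variant_columns == ()

    def test_table1_f_r_vs_l_i_variants(self):
        report = conservation(
            {
                "this-study": HEPCIDIN,
                "AAT95397.1": "DTHFPICIFCCGCCKTPKCGLCCIT",
            }
        )
        assert report.identity_matrix.loc[
            "this-study", "AAT95397.1"
        ] == pytest.approx(92.0)
        assert report.variant_columns == (21, 24)

    def test_table1_f_k_variant(self):
        report = conservation(
            {
                "this-study": HEPCIDIN,
                "AAW82336.1": "DTHFPICIFCCGCCKTPKCGFCCKT",
            }
        )
        assert report.identity_matrix.loc[
            "this-study", "AAW82336.1"
        ] == pytest.approx(96.0)
        assert report.variant_columns == (24,)

    def test_matrix_invariant_under_reordering(self):
        seqs = {
            "a": HEPCIDIN,
            "b": "DTHFPICIFCCGCCKTPKCGLCCIT",
            "c": "DTHFPICIFCCGCCKTPKCGFCCKT",
        }
        fwd = conservation(seqs)
        rev = conservation(dict(reversed(list(seqs.items()))))
        for i in seqs:
            for j in seqs:
                assert fwd.identity_matrix.loc[i, j] == pytest.approx(
                    rev.identity_matrix.loc[i, j]
                )

    def test_matrix_symmetric_with_unit_diagonal(self):
        report = conservation(
            {"a": HEPCIDIN, "b": "DTHFPICIFCCGCCKTPKCGLCCKT"}
        )
        mat = report.identity_matrix
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 100.0).all()

    def test_unequal_lengths_aligned_first(self):
        report = conservation({"full": HEPCIDIN, "trunc": HEPCIDIN[:20]})
        ident = report.identity_matrix.loc["full", "trunc"]
        assert ident == pytest.approx(80.0, abs=1.0)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            conservation({"a": HEPCIDIN})
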