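import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeosort.haplotypes import (
    classify_heterozygosity,
    collapse_to_iupac,
    extract_allele_sequences,
    majority_consensus,
    mask_interallelic_snps,
    trim_alignment,
)
from homeosort.io import (
    AlleleAlignment,
    PhasedVariantTable,
    SampleConfig,
    SequenceRecord,
    VariantRow,
)

REF = SequenceRecord("locus1", "ACGTACGT")
TET = SampleConfig("T1", "TET", 4, "tetraploid")
DIP = SampleConfig("D1", "DIP", 2, "diploid")


def row(pos, ref, alt, haps, ps=1, phased=True):
    return VariantRow(pos, ref, (alt,), tuple(haps), ps, phased)


class TestExtractAlleleSequences:
    def test_single_block_substitution(self):
        table = PhasedVariantTable(
            {"T1": [row(2, "C", "T", (0, 0, 1, 1)), row(5, "A", "G", (0, 1, 0, 1))]}
        )
        out = extract_allele_sequences(REF, table, TET)
        assert out.sequences == ["ACGTACGT", "ACGTGCGT", "ATGTACGT", "ATGTGCGT"]
        assert out.n_masked == 0 and out.het_class == "het_4"

    def test_out_of_block_site_masked_in_all_haplotypes(self):
        table = PhasedVariantTable(
            {
                "T1": [
                    row(2, "C", "T", (0, 0, 1, 1), ps=1),
                    row(5, "A", "G", (0, 1, 0, 1), ps=1),
                    row(7, "G", "A", (0, 1, 1, 0), ps=7),  # smaller block
                ]
            }
        )
        out = extract_allele_sequences(REF, table, TET)
        assert all(seq[6] == "N" for seq in out.sequences)
        assert [seq[:6] for seq in out.sequences] == [
            "ACGTAC", "ACGTGC", "ATGTAC", "ATGTGC"
        ]
        assert out.n_masked == 1

    def test_unphased_het_masked_but_hom_alt_applied(self):
        table = PhasedVariantTable(
            {
                "T1": [
                    row(2, "C", "T", (0, 1, 0, 1), phased=False, ps=None),
                    row(5, "A", "G", (1, 1, 1, 1), phased=False, ps=None),
                ]
            }
        )
        out = extract_allele_sequences(REF, table, TET)
        assert all(seq == "ANGTGCGT" for seq in out.sequences)
        assert out.n_masked == 1

    def test_keep_unphased_flag_applies_gt_order(self):
        table = PhasedVariantTable(
            {"T1": [row(2, "C", "T", (0, 1, 0, 1), phased=False, ps=None)]}
        )
        out = extract_allele_sequences(REF, table, TET, mask_unphased=False)
        assert [seq[1] for seq in out.sequences] == ["C", "T", "C", "T"]

    def test_block_tie_broken_by_smallest_phase_set(self):
        table = PhasedVariantTable(
            {
                "T1": [
                    row(2, "C", "T", (0, 0, 1, 1), ps=5),
                    row(5, "A", "G", (0, 1, 0, 1), ps=2),
                ]
            }
        )
        out = extract_allele_sequences(REF, table, TET)
        # ps=2 wins the tie: position 5 substituted, position 2 masked
        assert {seq[4] for seq in out.sequences} == {"A", "G"}
        assert all(seq[1] == "N" for seq in out.sequences)

    def test_diploid_homozygous_variants_only(self):
        table = PhasedVariantTable(
            {"D1": [row(3, "G", "C", (1, 1), phased=False, ps=None)]}
        )
        out = extract_allele_sequences(REF, table, DIP)
        assert out.sequences == ["ACCTACGT", "ACCTACGT"]
        assert out.het_class == "diploid_hom"

    def test_non_snp_rejected(self):
        table = PhasedVariantTable({"T1": [VariantRow(2, "C", ("CAT",), (0, 0, 1, 1), 1, True)]})
        with pytest.raises(ValueError, match="non-SNP"):
            extract_allele_sequences(REF, table, TET)

    def test_masked_columns_equal_het_variants_outside_block(self):
        table = PhasedVariantTable(
            {
                "T1": [
                    row(1, "A", "G", (0, 1, 1, 0), ps=1),
                    row(2, "C", "T", (0, 0, 1, 1), ps=1),
                    row(5, "A", "G", (0, 1, 0, 1), ps=9),
                    row(7, "G", "A", (1, 0, 0, 0), phased=False, ps=None),
                ]
            }
        )
        out = extract_allele_sequences(REF, table, TET)
        n_cols_masked = sum(
            1 for col in zip(*out.sequences) if set(col) == {"N"}
        )
        assert out.n_masked == n_cols_masked == 2


class TestClassifyHeterozygosity:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["X", "X", "X", "X"], "homozygous"),
            (["X", "X", "X", "Y"], "het_1_3"),
            (["X", "X", "Y", "Y"], "het_2_2"),
            (["X", "X", "Y", "Z"], "het_3"),
            (["W", "X", "Y", "Z"], "het_4"),
            (["X", "X"], "diploid_hom"),
            (["X", "Y"], "diploid_het"),
        ],
    )
    def test_patterns(self, seqs, expected):
        assert classify_heterozygosity(seqs) == expected

    @given(st.permutations(["AC", "AC", "AG", "TT"]))
    @settings(max_examples=24, deadline=None)
    def test_invariant_to_allele_order(self, seqs):
        assert classify_heterozygosity(list(seqs)) == "het_3"


class TestMaskInterallelicSnps:
    @pytest.mark.parametrize(
        "seqs,expected,n",
        [
            (["ACGT", "ACGA"], "ACGN", 1),
            (["ACGT", "ACGT", "ACGT", "ACGT"], "ACGT", 0),
            (["ANGT", "ACGT"], "ACGT", 0),  # N transparent, non-N agree
            (["NNNN", "NNNN"], "NNNN", 0),
        ],
    )
    def test_rule(self, seqs, expected, n):
        assert mask_interallelic_snps(seqs) == (expected, n)

    @given(
        st.lists(
            st.text(alphabet="ACGTN-", min_size=6, max_size=6),
            min_size=2, max_size=4,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_idempotent_and_erases_disagreement(self, seqs):
        masked, _ = mask_interallelic_snps(seqs)
        assert mask_interallelic_snps([masked])[0] == masked
        for col, out in zip(zip(*seqs), masked):
            residues = {c for c in col if c != "N"}
            if len(residues) > 1:
                assert out == "N"


class TestCollapseAndConsensus:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ACGT", "ATGT"], "AYGT"),
            (["ACGT", "ACGT"], "ACGT"),
            (["AC-T", "ACGT"], "ACNT"),
            (["ACGT", "AGGT", "ATGT"], "ABGT"),  # C+G+T -> B
        ],
    )
    def test_iupac_collapse(self, seqs, expected):
        assert collapse_to_iupac(seqs) == expected

    @given(st.text(alphabet="ACGT-", min_size=1, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_iupac_of_single_sequence_is_identity(self, seq):
        assert collapse_to_iupac([seq]) == seq

    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ACGT", "ACGT", "ATGT"], "ACGT"),
            (["ACGT", "ATGT"], "AYGT"),  # tie -> IUPAC
            (["NNNN", "ACGT"], "ACGT"),  # N transparent
        ],
    )
    def test_majority_consensus(self, seqs, expected):
        assert majority_consensus(seqs) == expected


class TestTrimAlignment:
    def aln(self, *seqs):
        return AlleleAlignment(
            "x", [SequenceRecord(f"s{i}__h1", s) for i, s in enumerate(seqs, 1)]
        )

    def test_strictly_greater_than_threshold_removed(self):
        # column 1: 2/4 gaps (removed); column 2: 1/4 gaps (kept, == 25%)
        trimmed, removed = trim_alignment(self.aln("-AG", "-AG", "AAG", "A-G"))
        assert removed == [1]
        assert [r.sequence for r in trimmed.records] == ["AG", "AG", "AG", "-G"]

    def test_all_gap_column_removed(self):
        trimmed, removed = trim_alignment(self.aln("A-T", "A-T"))
        assert removed == [2] and trimmed.length == 2

    def test_empty_result_flagged(self):
        trimmed, removed = trim_alignment(self.aln("--", "--"))
        assert trimmed.length == 0 and removed == [1, 2]
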