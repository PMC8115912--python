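import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeosort import SimScenario, simulate_dataset
from homeosort.distances import DistanceMatrix
from homeosort.io import SampleConfig, SamplesTable
from homeosort.pipeline import process_exon
from homeosort.sorting import (
    enumerate_pairings,
    homeolog_reference_distances,
    label_homeologs,
    sort_alleles,
)

from _oracle import brute_force_sort, random_matrix_cases

LABELS = ["a1", "a2", "a3", "a4"]


def pairs_dict(within=0.01, cross=0.10):
    """(a1,a2) and (a3,a4) are the close pairs; the 4 cross pairs share one value."""
    d = {
        frozenset(("a1", "a2")): within,
        frozenset(("a3", "a4")): within,
    }
    for p in [("a1", "a3"), ("a1", "a4"), ("a2", "a3"), ("a2", "a4")]:
        d[frozenset(p)] = cross
    return d


class TestEnumeratePairings:
    def test_three_matchings_deterministic(self):
        pairings = enumerate_pairings(LABELS)
        assert [p.pairs for p in pairings] == [
            (("a1", "a2"), ("a3", "a4")),
            (("a1", "a3"), ("a2", "a4")),
            (("a1", "a4"), ("a2", "a3")),
        ]

    def test_each_pair_appears_exactly_once(self):
        seen = [frozenset(p) for pairing in enumerate_pairings(LABELS) for p in pairing.pairs]
        assert sorted(map(sorted, seen)) == sorted(
            map(sorted, itertools.combinations(LABELS, 2))
        )

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairings(["a", "b", "c"])


class TestSortAlleles:
    def test_clear_separation_sorted(self, make_matrix):
        D = make_matrix(LABELS, pairs_dict(0.01, 0.10))
        dec = sort_alleles(D, "l", "s")
        assert dec.status == "sorted"
        assert dec.s_best == pytest.approx(0.01)
        assert dec.s_second == pytest.approx(0.10)
        assert dec.ratio == pytest.approx(10.0)
        assert set(map(frozenset, dec.pairing.pairs)) == {
            frozenset(("a1", "a2")), frozenset(("a3", "a4"))
        }

    def test_ratio_at_most_threshold_is_equivocal(self, make_matrix):
        dec = sort_alleles(make_matrix(LABELS, pairs_dict(0.01, 0.03)), "l", "s")
        assert dec.status == "equivocal"
        assert dec.ratio == pytest.approx(3.0)

    def test_exact_threshold_fails_strict_inequality(self, make_matrix):
        dec = sort_alleles(make_matrix(LABELS, pairs_dict(0.01, 0.04)), "l", "s")
        assert dec.status == "equivocal"

    def test_all_zero_is_homozygous_like(self, make_matrix):
        dec = sort_alleles(make_matrix(LABELS, pairs_dict(0.0, 0.0)), "l", "s")
        assert dec.status == "homozygous_like"

    def test_zero_best_with_positive_alternatives_sorts_with_infinite_ratio(
        self, make_matrix
    ):
        dec = sort_alleles(make_matrix(LABELS, pairs_dict(0.0, 0.08)), "l", "s")
        assert dec.status == "sorted" and dec.ratio == math.inf

    def test_missing_distance_is_insufficient_overlap(self):
        values = np.full((4, 4), 0.1)
        np.fill_diagonal(values, 0.0)
        values[0, 1] = values[1, 0] = np.nan
        dec = sort_alleles(DistanceMatrix(tuple(LABELS), values), "l", "s")
        assert dec.status == "insufficient_overlap"

    def test_monotone_in_threshold(self, make_matrix):
        rng = np.random.default_rng(7)
        for dist in random_matrix_cases(rng, 300):
            D = make_matrix(list(range(4)), dist)
            statuses = [
                sort_alleles(D, threshold=t).status for t in (2.0, 4.0, 8.0)
            ]
            sorted_at = [s == "sorted" for s in statuses]
            # sorted at a higher threshold implies sorted at every lower one
            assert sorted_at[2] <= sorted_at[1] <= sorted_at[0]

    def test_permuting_allele_order_never_changes_the_decision(self, make_matrix):
        rng = np.random.default_rng(21)
        for dist in random_matrix_cases(rng, 30):
            decisions = []
            for perm in itertools.permutations(range(4)):
                D = make_matrix(list(perm), dist)
                dec = sort_alleles(D)
                key = (
                    dec.status,
                    None
                    if dec.status != "sorted"
                    else frozenset(frozenset(p) for p in dec.pairing.pairs),
                )
                decisions.append(key)
            assert len(set(decisions)) == 1

    @given(values=st.lists(st.floats(0.0, 1.0), min_size=6, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_pairing_scores_sum_to_total_distance(self, values):
        from conftest import matrix_from_pairs

        dist = dict(zip((frozenset(p) for p in itertools.combinations(LABELS, 2)), values))
        D = matrix_from_pairs(LABELS, dist)
        pairings = enumerate_pairings(LABELS)
        total = sum(
            D.get(*pair) for p in pairings for pair in p.pairs
        )
        assert total == pytest.approx(sum(values), abs=1e-12)

    def test_agrees_with_brute_force_oracle(self, make_matrix):
        rng = np.random.default_rng(13)
        labels = list(range(4))
        for dist in random_matrix_cases(rng, 1000):
            D = make_matrix(labels, dist)
            dec = sort_alleles(D)
            status, matching, ratio = brute_force_sort(
                labels, {k: v for k, v in dist.items()}
            )
            assert dec.status == status
            if status == "sorted":
                ours = frozenset(
                    frozenset(int(x) for x in p) for p in dec.pairing.pairs
                )
                assert ours == matching
                if math.isinf(ratio):
                    assert math.isinf(dec.ratio)
                else:
                    assert dec.ratio == pytest.approx(ratio, rel=1e-9)


class TestLabelHomeologs:
    def full_matrix(self, make_matrix, ref_close_to_first=True):
        labels = LABELS + ["r1", "r2"]
        dist = pairs_dict(0.01, 0.10)
        near, far = (0.02, 0.08) if ref_close_to_first else (0.08, 0.02)
        for a in ("a1", "a2"):
            for r in ("r1", "r2"):
                dist[frozenset((a, r))] = near
        for a in ("a3", "a4"):
            for r in ("r1", "r2"):
                dist[frozenset((a, r))] = far
        dist[frozenset(("r1", "r2"))] = 0.01
        return make_matrix(labels, dist)

    def decision(self, make_matrix):
        return sort_alleles(make_matrix(LABELS, pairs_dict(0.01, 0.10)), "l", "s")

    def test_closer_pair_labelled_a(self, make_matrix):
        dec = label_homeologs(
            self.decision(make_matrix), self.full_matrix(make_matrix), ["r1", "r2"]
        )
        assert dec.status == "sorted"
        assert set(dec.pair_a) == {"a1", "a2"}
        assert dec.dist_a_ref == pytest.approx(0.02)
        assert dec.dist_b_ref == pytest.approx(0.08)

    def test_swapping_reference_swaps_labels(self, make_matrix):
        dec = label_homeologs(
            self.decision(make_matrix),
            self.full_matrix(make_matrix, ref_close_to_first=False),
            ["r1", "r2"],
        )
        assert set(dec.pair_a) == {"a3", "a4"}

    def test_absent_reference_is_equivocal(self, make_matrix):
        dec = label_homeologs(
            self.decision(make_matrix), self.full_matrix(make_matrix), ["zz"]
        )
        assert dec.status == "equivocal" and dec.reason == "no_reference"

    def test_reference_tie_downgrades(self, make_matrix):
        labels = LABELS + ["r1"]
        dist = pairs_dict(0.01, 0.10)
        for a in LABELS:
            dist[frozenset((a, "r1"))] = 0.05
        dec = label_homeologs(
            self.decision(make_matrix), make_matrix(labels, dist), ["r1"]
        )
        assert dec.status == "equivocal" and dec.reason == "label_tie"


class TestReferenceSwapSymmetry:
    def test_maternal_vs_paternal_reference_swaps_every_locus(self):
        dataset = simulate_dataset(SimScenario(n_loci=25, seed=3))
        maternal = dataset.samples
        paternal = SamplesTable(
            [
                SampleConfig("M1", "M1", 2, "diploid"),
                SampleConfig("M2", "M2", 2, "diploid"),
                SampleConfig("P1", "P1", 2, "reference_taxon_member"),
                SampleConfig("P2", "P2", 2, "diploid"),
                SampleConfig("OUT", "OUT", 2, "outgroup"),
                SampleConfig("T1", "TET", 4, "tetraploid"),
            ]
        )
        for locus_id in sorted(dataset.alignments):
            aln = dataset.alignments[locus_id]
            dec_m = process_exon(aln, maternal).decisions["T1"]
            dec_p = process_exon(aln, paternal).decisions["T1"]
            assert dec_m.status == dec_p.status == "sorted"
            assert set(dec_m.pair_a) == set(dec_p.pair_b)
            assert set(dec_m.pair_b) == set(dec_p.pair_a)


class TestHomeologReferenceDistances:
    def test_single_locus_hand_means(self, samples_table, make_matrix):
        labels = ["T1__h1", "T1__h2", "T1__h3", "T1__h4", "M1__h1", "P1__h1"]
        dist = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                dist[frozenset((a, b))] = 0.5
        dist[frozenset(("T1__h1", "T1__h2"))] = 0.01
        dist[frozenset(("T1__h3", "T1__h4"))] = 0.01
        dist[frozenset(("T1__h1", "M1__h1"))] = 0.02
        dist[frozenset(("T1__h2", "M1__h1"))] = 0.04
        dist[frozenset(("T1__h3", "P1__h1"))] = 0.03
        dist[frozenset(("T1__h4", "P1__h1"))] = 0.05
        D = make_matrix(labels, dist)
        dec = sort_alleles(D.submatrix(labels[:4]), "l1", "T1")
        dec = label_homeologs(dec, D, ["M1__h1"])
        table = homeolog_reference_distances([dec], {"l1": D}, samples_table)
        assert table.loc[("T1", "A"), "M1"] == pytest.approx((0.02 + 0.04) / 2)
        assert table.loc[("T1", "B"), "P1"] == pytest.approx((0.03 + 0.05) / 2)
        assert table.loc[("T1", "B"), "M1"] == pytest.approx(0.5)

    def test_no_sorted_loci_gives_empty_table(self, samples_table):
        table = homeolog_reference_distances([], {}, samples_table)
        assert table.empty

    def test_ranks_maternal_clade_closest_to_homeolog_a(self, default_dataset):
        decisions = []
        matrices = {}
        for locus_id in sorted(default_dataset.alignments):
            result = process_exon(
                default_dataset.alignments[locus_id], default_dataset.samples
            )
            matrices[locus_id] = result.distances
            decisions.extend(result.decisions.values())
        table = homeolog_reference_distances(
            decisions, matrices, default_dataset.samples
        )
        a_row = table.loc[("T1", "A")]
        b_row = table.loc[("T1", "B")]
        assert set(a_row.nsmallest(2).index) == {"M1", "M2"}
        assert set(b_row.nsmallest(2).index) == {"P1", "P2"}
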