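import math

import numpy as np
import pytest

import barcodeval as bv


def matrix_from(labels, species, pairs):
    """Build a DistanceMatrix from explicit pair distances (NaN = undefined)."""
    n = len(labels)
    d = np.zeros((n, n))
    sites = np.full((n, n), 100, dtype=np.int64)
    for (a, b), v in pairs.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
        if math.isnan(v):
            sites[i, j] = sites[j, i] = 0
    return bv.DistanceMatrix(list(labels), list(species), d, sites)


class TestThreshold:
    def test_ninety_five_percent_point_of_twenty_values(self):
        t = bv.compute_threshold([0.01] * 19 + [0.50], percentile=0.95)
        assert t.value == 0.01
        assert t.n_intra_pairs == 20

    def test_constant_distances(self):
        assert bv.compute_threshold([0.02, 0.02, 0.02]).value == 0.02

    def test_single_value(self):
        assert bv.compute_threshold([0.03]).value == 0.03

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bv.compute_threshold([])

    def test_smallest_qualifying_observed_value_on_random_lists(self, rng):
        # brute-force oracle: scan observed values in increasing order
        for _ in range(200):
            vals = rng.uniform(0, 0.2, size=int(rng.integers(1, 40)))
            t = bv.compute_threshold(vals, 0.95)
            qualifying = [
                v for v in sorted(vals) if (vals <= v).sum() / vals.size >= 0.95
            ]
            assert t.value == qualifying[0]
            assert (vals <= t.value).mean() >= 0.95


THRESH = bv.BCMThreshold(value=0.05, percentile=0.95, n_intra_pairs=10)


class TestClassifyQuery:
    def test_nearest_conspecific_within_threshold_is_correct(self):
        m = matrix_from(
            ["q", "same", "other"],
            ["A", "A", "B"],
            {("q", "same"): 0.01, ("q", "other"): 0.04, ("same", "other"): 0.2},
        )
        r = bv.classify_query("q", m, THRESH)
        assert r.category == "correct"
        assert r.best_match_id == "same"
        assert r.best_distance == pytest.approx(0.01)

    def test_tie_between_conspecific_and_heterospecific_is_ambiguous(self):
        m = matrix_from(
            ["q", "same", "other"],
            ["A", "A", "B"],
            {("q", "same"): 0.02, ("q", "other"): 0.02, ("same", "other"): 0.2},
        )
        assert bv.classify_query("q", m, THRESH).category == "ambiguous"

    def test_only_heterospecifics_within_threshold_is_incorrect(self):
        m = matrix_from(
            ["q", "same", "other"],
            ["A", "A", "B"],
            {("q", "same"): 0.30, ("q", "other"): 0.02, ("same", "other"): 0.2},
        )
        assert bv.classify_query("q", m, THRESH).category == "incorrect"

    def test_nothing_within_threshold_is_no_match(self):
        m = matrix_from(
            ["q", "same", "other"],
            ["A", "A", "B"],
            {("q", "same"): 0.30, ("q", "other"): 0.25, ("same", "other"): 0.2},
        )
        r = bv.classify_query("q", m, THRESH)
        assert r.category == "no_match"
        assert r.best_match_id is None

    def test_undefined_distance_is_never_a_candidate(self):
        m = matrix_from(
            ["q", "same", "other"],
            ["A", "A", "B"],
            {("q", "same"): float("nan"), ("q", "other"): 0.02, ("same", "other"): 0.2},
        )
        assert bv.classify_query("q", m, THRESH).category == "incorrect"

    def test_singleton_query_flagged(self):
        m = matrix_from(
            ["q", "b1", "b2"],
            ["A", "B", "B"],
            {("q", "b1"): 0.01, ("q", "b2"): 0.02, ("b1", "b2"): 0.01},
        )
        r = bv.classify_query("q", m, THRESH)
        assert r.is_singleton and r.category == "incorrect"

    def test_absent_query_raises(self):
        m = matrix_from(["a", "b"], ["A", "B"], {("a", "b"): 0.1})
        with pytest.raises(KeyError):
            bv.classify_query("ghost", m, THRESH)

    def test_raising_threshold_never_creates_no_match(self, rng):
        # monotonicity: candidates only grow with the threshold
        for _ in range(30):
            n = 8
            labels = [f"s{i}" for i in range(n)]
            species = [f"Sp{i % 3}" for i in range(n)]
            d = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            vals = rng.uniform(0, 0.3, len(iu[0]))
            d[iu] = vals
            d = d + d.T
            m = bv.DistanceMatrix(labels, species, d, np.full((n, n), 50))
            lo = bv.BCMThreshold(0.05, 0.95, 10)
            hi = bv.BCMThreshold(0.15, 0.95, 10)
            for q in labels:
                if bv.classify_query(q, m, lo).category != "no_match":
                    assert bv.classify_query(q, m, hi).category != "no_match"

    def test_agrees_with_nearest_neighbour_oracle_when_distances_distinct(self, rng):
        # with tie_tol=0 and all distances distinct the tie set is a singleton,
        # so the rule reduces to threshold + nearest neighbour
        for _ in range(50):
            n = 7
            labels = [f"s{i}" for i in range(n)]
            species = [f"Sp{i % 3}" for i in range(n)]
            iu = np.triu_indices(n, 1)
            vals = rng.permutation(len(iu[0])) * 0.01 + 0.005  # distinct
            d = np.zeros((n, n))
            d[iu] = vals
            d = d + d.T
            m = bv.DistanceMatrix(labels, species, d, np.full((n, n), 50))
            t = bv.BCMThreshold(0.12, 0.95, 10)
            for qi, q in enumerate(labels):
                r = bv.classify_query(q, m, t, tie_tol=0.0)
                row = d[qi].copy()
                row[qi] = np.inf
                if row.min() > t.value:
                    assert r.category == "no_match"
                else:
                    nn = int(np.argmin(row))
                    expected = (
                        "correct" if species[nn] == species[qi] else "incorrect"
                    )
                    assert r.category == expected
                    assert r.best_match_id == labels[nn]


class TestBCMSummary:
    def test_clean_two_species_design_all_correct(self, toy_alignment):
        report = bv.bcm_summary(toy_alignment)
        assert report.percentages()["correct"] == 100.0
        assert report.threshold.value == 0.0
        assert report.n_singleton_queries == 0

    def test_identical_specimens_across_species_all_ambiguous(self):
        aln = bv.MarkerAlignment(
            "t",
            ["a1", "a2", "b1", "b2"],
            ["Aus alba", "Aus alba", "Aus bella", "Aus bella"],
            ["ACGT"] * 4,
        )
        assert bv.bcm_summary(aln).percentages()["ambiguous"] == 100.0

    def test_divergent_species_beyond_threshold_is_no_match(self):
        # species Y sits far from everything; its two specimens differ from
        # each other more than the threshold set by species X's intra pairs
        aln = bv.MarkerAlignment(
            "t",
            [f"x{i}" for i in range(7)] + ["y1", "y2"],
            ["X"] * 7 + ["Y", "Y"],
            ["AAAAAAAAAA"] * 7 + ["TTTTTTTTTT", "TTTTTCCCCC"],
        )
        report = bv.bcm_summary(aln)
        by_id = {r.query_id: r.category for r in report.results}
        assert by_id["y1"] == by_id["y2"] == "no_match"

    def test_percentages_sum_to_100(self, rng):
        from conftest import random_alignment

        for _ in range(10):
            aln = random_alignment(rng, n_rows=8, n_cols=20, missing_frac=0.05)
            try:
                report = bv.bcm_summary(aln)
            except ValueError:
                continue  # no usable intra pairs in this draw
            assert sum(report.percentages().values()) == pytest.approx(100.0, abs=0.1)

    def test_single_species_rejected(self):
        aln = bv.MarkerAlignment("t", ["a", "b"], ["X", "X"], ["ACGT", "ACGA"])
        with pytest.raises(ValueError):
            bv.bcm_summary(aln)
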