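"""Filtering, normalization, the moderated NB test, BH-FDR, and Venn overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from wregion.counts_de import (
    ContrastSpec,
    CountMatrix,
    bh_adjust,
    de_overlap,
    filter_low_counts,
    log2_cpm,
    median_ratio_size_factors,
    nb_two_group_test,
)

from conftest import make_count_matrix


class TestCountMatrix:
    def test_rejects_duplicates_and_negatives(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            make_count_matrix(np.ones((2, 2)), ["a", "a"], gene_ids=["g", "g"])
        with pytest.raises(ValueError, match="non-negative"):
            make_count_matrix(np.array([[-1, 2]]), ["a", "a"])

    def test_tsv_round_trip(self, tiny_cm, tmp_path):
        tiny_cm.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert (back.counts == tiny_cm.counts).all().all()
        assert list(back.samples["group"]) == list(tiny_cm.samples["group"])


class TestFilterLowCounts:
    def test_mean_rule_boundary(self):
        cm = make_count_matrix(np.array([[1, 2, 2, 2], [2, 2, 2, 2]]),
                               ["a", "a", "b", "b"])
        kept = filter_low_counts(cm, min_mean=2)
        assert kept.gene_ids == ["g1"]  # mean 1.75 removed, mean 2.0 retained

    def test_zero_threshold_is_identity(self, tiny_cm):
        assert filter_low_counts(tiny_cm, min_mean=0).gene_ids == tiny_cm.gene_ids

    def test_matches_per_gene_mean_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(50, 8))
        cm = make_count_matrix(counts, ["a"] * 4 + ["b"] * 4)
        kept = set(filter_low_counts(cm, min_mean=2).gene_ids)
        oracle = {f"g{i}" for i in range(50) if counts[i].mean() >= 2}
        assert kept == oracle

    def test_empty_matrix_rejected(self):
        cm = make_count_matrix(np.ones((1, 2)), ["a", "a"])
        empty = CountMatrix(cm.counts.iloc[:0], cm.samples)
        with pytest.raises(ValueError, match="empty"):
            filter_low_counts(empty)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 3, 50])
        cm = make_count_matrix(np.tile(col[:, None], 4), ["a"] * 2 + ["b"] * 2)
        factors = median_ratio_size_factors(cm)
        assert np.allclose(factors, 1.0)

    def test_doubled_column_doubles_relative_factor(self):
        col = np.array([5, 10, 3, 50])
        counts = np.tile(col[:, None], 4)
        counts[:, 0] *= 2
        cm = make_count_matrix(counts, ["a"] * 2 + ["b"] * 2)
        factors = median_ratio_size_factors(cm).to_numpy()
        assert factors[0] / factors[1] == pytest.approx(2.0)
        assert np.allclose(factors[1:], factors[1])

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(20, size=(30, 5)) + 1
        cm = make_count_matrix(counts, ["a"] * 3 + ["b"] * 2)
        factors = median_ratio_size_factors(cm).to_numpy()
        geo = np.exp(np.log(counts).mean(axis=1))
        oracle = np.median(counts / geo[:, None], axis=0)
        assert np.allclose(factors, oracle)

    def test_all_zero_sample_named_in_error(self):
        counts = np.array([[1, 0], [2, 0]])
        cm = make_count_matrix(counts, ["a", "b"], sample_ids=["ok", "dead"])
        with pytest.raises(ValueError, match="dead"):
            median_ratio_size_factors(cm)


class TestLog2Cpm:
    def test_zero_count_maps_to_log2_prior(self):
        cm = make_count_matrix(np.array([[0, 4], [10, 6]]), ["a", "b"])
        lib = pd.Series([10.0, 10.0], index=cm.sample_ids)
        out = log2_cpm(cm, prior=0.5, lib_sizes=lib)
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5))

    def test_doubling_counts_and_libsize_is_invariant(self):
        counts = np.array([[3, 7], [11, 2]])
        cm = make_count_matrix(counts, ["a", "b"])
        lib = pd.Series([100.0, 80.0], index=cm.sample_ids)
        base = log2_cpm(cm, lib_sizes=lib)
        doubled = counts.copy()
        doubled[:, 0] *= 2
        cm2 = make_count_matrix(doubled, ["a", "b"])
        lib2 = lib.copy()
        lib2.iloc[0] *= 2
        assert np.allclose(log2_cpm(cm2, lib_sizes=lib2), base)

    def test_hand_computed_values(self):
        cm = make_count_matrix(np.array([[2, 8], [6, 4]]), ["a", "b"])
        lib = pd.Series([8.0, 12.0], index=cm.sample_ids)
        out = log2_cpm(cm, prior=0.5, lib_sizes=lib)
        assert out.iloc[0, 0] == pytest.approx(np.log2(2 / 8 * 1e6 + 0.5))
        assert out.iloc[1, 1] == pytest.approx(np.log2(4 / 12 * 1e6 + 0.5))

    def test_nonpositive_prior_rejected(self, tiny_cm):
        with pytest.raises(ValueError, match="prior"):
            log2_cpm(tiny_cm, prior=0.0)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_textbook_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_nan_propagates_without_entering_m(self):
        out = bh_adjust([0.02, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_adjust([0.02, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_stepup_oracle_and_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        out = bh_adjust(ps)
        # Brute-force step-up definition.
        arr = np.asarray(ps)
        m = arr.size
        order = np.argsort(arr, kind="mergesort")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, arr[order[rank - 1]] * m / rank)
            expected[order[rank - 1]] = running
        assert np.allclose(out, expected)
        assert np.allclose(out, multipletests(arr, method="fdr_bh")[1])
        assert (out >= arr - 1e-15).all()

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.sampled_from([0.05, 0.1, 0.2]))
    def test_rejection_set_equals_classical_bh(self, ps, q):
        # Classical step-up: find the largest i with p_(i) * m / i <= q and
        # reject everything up to p_(i); this must coincide with thresholding
        # the adjusted values at q.
        arr = np.asarray(ps)
        adjusted = bh_adjust(arr)
        m = arr.size
        srt = np.sort(arr)
        k = max([i + 1 for i in range(m) if srt[i] * m / (i + 1) <= q], default=0)
        classical = set(np.where(arr <= (srt[k - 1] if k else -1.0))[0])
        assert set(np.where(adjusted <= q)[0]) == classical


class TestNBTwoGroupTest:
    def test_identical_groups_give_zero_logfc(self):
        block = np.array([[10, 14, 12], [3, 5, 2], [40, 44, 39]])
        counts = np.hstack([block, block])
        cm = make_count_matrix(counts, ["t"] * 3 + ["r"] * 3)
        res = nb_two_group_test(cm, ContrastSpec("t", "r"), min_mean=None)
        assert np.allclose(res.table.log2fc, 0.0)
        assert (res.table.p_value == 1.0).all()

    def test_zero_in_both_groups_gene(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        cm = make_count_matrix(counts, ["t", "t", "r", "r"])
        res = nb_two_group_test(cm, ContrastSpec("t", "r"), min_mean=None)
        assert res.table.log2fc.iloc[0] == 0.0
        assert res.table.p_value.iloc[0] == 1.0

    def test_poisson_limit_se_closed_form(self):
        # Constant within-group columns make every dispersion estimate zero,
        # so the Wald SE collapses to the Poisson delta-method form. Nine
        # flat genes pin the median-of-ratios factors at 1.
        flat = np.full((9, 6), 7)
        de = np.array([[40, 40, 40, 10, 10, 10]])
        cm = make_count_matrix(np.vstack([de, flat]), ["t"] * 3 + ["r"] * 3)
        res = nb_two_group_test(cm, ContrastSpec("t", "r"), min_mean=None)
        pc = 0.5
        mu_t, mu_r, n = 40.0, 10.0, 3
        se = np.sqrt((1 / (mu_t + pc)) / n + (1 / (mu_r + pc)) / n)
        z = np.log((mu_t + pc) / (mu_r + pc)) / se
        expected_p = 2 * stats.norm.sf(abs(z))
        assert res.table.p_value.iloc[0] == pytest.approx(expected_p, rel=1e-9)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(15, size=(40, 8))
        cm = make_count_matrix(counts, ["t"] * 4 + ["r"] * 4)
        res = nb_two_group_test(cm, ContrastSpec("t", "r"))
        perm = rng.permutation(40)
        shuffled = CountMatrix(cm.counts.iloc[perm], cm.samples)
        res2 = nb_two_group_test(shuffled, ContrastSpec("t", "r"))
        aligned = res2.table.loc[res.table.index]
        pd.testing.assert_frame_equal(res.table, aligned)

    def test_filtered_genes_marked_not_dropped(self):
        counts = np.array([[0, 1, 0, 1], [30, 28, 33, 31]])
        cm = make_count_matrix(counts, ["t", "t", "r", "r"])
        res = nb_two_group_test(cm, ContrastSpec("t", "r"), min_mean=2)
        assert list(res.table.index) == ["g0", "g1"]
        assert bool(res.table.filtered.iloc[0]) is True
        assert np.isnan(res.table.log2fc.iloc[0])
        assert bool(res.table.de_flag.iloc[0]) is False

    def test_de_flag_matches_fdr_threshold(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(20, size=(200, 12))
        counts[:10, :6] *= 6  # strong signal for ten genes
        cm = make_count_matrix(counts, ["t"] * 6 + ["r"] * 6)
        res = nb_two_group_test(cm, ContrastSpec("t", "r"), alpha=0.10)
        tab = res.table[~res.table.filtered]
        assert (tab.de_flag == (tab.fdr < 0.10)).all()
        assert (tab.fdr >= tab.p_value - 1e-12).all()

    def test_same_group_contrast_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            ContrastSpec("a", "a")

    def test_single_sample_group_warns(self):
        cm = make_count_matrix(np.array([[5, 6, 7], [8, 9, 10]]), ["t", "r", "r"])
        with pytest.warns(UserWarning, match="single sample"):
            nb_two_group_test(cm, ContrastSpec("t", "r"), min_mean=None)


class TestDeOverlap:
    def test_two_set_example(self):
        out = de_overlap({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert out == {"A": 1, "B": 1, "A&B": 2}

    def test_identical_sets_fall_in_full_intersection(self):
        out = de_overlap({"X": {"a", "b"}, "Y": {"a", "b"}, "Z": {"a", "b"}})
        assert out["X&Y&Z"] == 2
        assert sum(out.values()) == 2

    def test_three_random_sets_match_membership_oracle(self):
        rng = np.random.default_rng(4)
        pool = [f"e{i}" for i in range(30)]
        sets = {n: {e for e in pool if rng.random() < 0.4} for n in "ABC"}
        out = de_overlap(sets)
        # Oracle: classify every element of the union by its membership tuple.
        expected = {label: 0 for label in out}
        for element in set().union(*sets.values()):
            members = tuple(n for n in "ABC" if element in sets[n])
            expected["&".join(members)] += 1
        assert out == expected
        assert sum(out.values()) == len(set().union(*sets.values()))

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            de_overlap([("A", {"x"}), ("A", {"y"})])

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            de_overlap({"A": {"x"}})
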