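"""Interaction statistics: BH, studentized outliers, rank-sum, enrichment models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from socascreen import (
    InteractionModel,
    MedianAbundanceSummary,
    bh_adjust,
    expected_dko_enrichment,
    observed_dko_enrichment,
    regression_cell_vs_tumour,
    studentized_outlier_test,
    synergy_by_enrichment,
    synergy_by_rank_test,
    wilcoxon_rank_sum,
)


def bh_brute_force(p):
    """Literal step-up definition: p_(i) * m / i, monotonized from the largest."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


class TestBhAdjust:
    def test_hand_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(bh_adjust(p), bh_brute_force(p))


def studentized_brute_force(x, y):
    """Externally studentized residuals via explicit hat matrix and
    leave-one-out residual variance."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    resid = y - H @ y
    h = np.diag(H)
    s2 = resid @ resid / (n - 2)
    # delete-one variance: s2_(i) = ((n-2) s2 - r_i^2/(1-h_i)) / (n-3)
    s2_loo = ((n - 2) * s2 - resid**2 / (1 - h)) / (n - 3)
    return resid / np.sqrt(s2_loo * (1 - h))


class TestStudentizedOutlierTest:
    def test_planted_outlier_ranks_first(self):
        x = np.arange(10.0)
        y = 2 * x
        y[7] += 10.0
        table = studentized_outlier_test(x, y)
        assert table.index[0] == 7
        assert table["p_adj"].iloc[0] == table["p_adj"].min()

    def test_perfect_fit_gives_unit_pvalues(self):
        x = np.arange(8.0)
        table = studentized_outlier_test(x, 3 * x + 1)
        assert np.allclose(table["studentized_residual"], 0.0, atol=1e-8)
        assert np.allclose(table["p"], 1.0)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=25)
        y = 1.5 * x + rng.normal(size=25)
        table = studentized_outlier_test(x, y).sort_index()
        expected = studentized_brute_force(x, y)
        assert np.allclose(table["studentized_residual"], expected)
        # p from a t reference with n - 3 degrees of freedom
        from scipy.stats import t as tdist

        assert np.allclose(table["p"], 2 * tdist.sf(np.abs(expected), df=22))

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            studentized_outlier_test([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            studentized_outlier_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def wilcoxon_enumeration_p(xs, ys):
    """Exact two-sided p by enumerating all rank assignments of the pooled data."""
    pooled = np.concatenate([xs, ys])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(xs)
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    total = 0
    as_extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        stat = ranks[list(combo)].sum()
        if abs(stat - mean) >= abs(observed - mean) - 1e-9:
            as_extreme += 1
    return as_extreme / total


class TestWilcoxonRankSum:
    def test_identical_samples_give_p_near_one(self):
        xs = np.array([1.0, 2.0, 3.0, 4.0] * 5)
        ys = xs.copy()
        _, p = wilcoxon_rank_sum(xs, ys)
        assert p >= 0.99

    def test_fully_separated_small_samples_exact_p(self):
        # most extreme of the C(6,3) = 20 orderings, doubled
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(4)
        xs, ys = rng.normal(size=6), rng.normal(size=8)
        assert wilcoxon_rank_sum(xs, ys)[1] == pytest.approx(wilcoxon_rank_sum(ys, xs)[1])

    @pytest.mark.parametrize("n1,n2", [(1, 9), (2, 8), (3, 7), (4, 6), (5, 5), (9, 1)])
    def test_exact_p_matches_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            xs = rng.normal(size=n1)
            ys = rng.normal(size=n2)
            _, p = wilcoxon_rank_sum(xs, ys)
            assert p == pytest.approx(wilcoxon_enumeration_p(xs, ys))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def make_summary(pair=("A", "B"), **kw):
    values = dict(D_t=1, D_c=1, A_t=1, A_c=1, B_t=1, B_c=1, N_t=1, N_c=1)
    values.update(kw)
    return MedianAbundanceSummary(pair=pair, **values)


class TestEnrichmentFormulas:
    def test_no_change_is_one(self):
        assert observed_dko_enrichment(make_summary(D_t=5, D_c=5, N_t=3, N_c=3)) == 1.0

    def test_direct_arithmetic(self):
        s = make_summary(D_t=2, D_c=8, N_c=10, N_t=5)
        assert observed_dko_enrichment(s) == pytest.approx(0.5)

    def test_ntc_like_dko_is_fixed_point(self):
        s = make_summary(D_t=6, D_c=3, N_t=4, N_c=2)  # D_t/D_c == N_t/N_c
        assert observed_dko_enrichment(s) == pytest.approx(1.0)

    def test_expected_two_neutral_genes_is_two(self):
        s = make_summary(A_t=3, A_c=3, B_t=7, B_c=7, N_t=2, N_c=2)
        assert expected_dko_enrichment(s) == pytest.approx(2.0)

    def test_expected_direct_arithmetic(self):
        s = make_summary(A_t=1, A_c=2, B_t=3, B_c=10, N_c=2, N_t=1)
        assert expected_dko_enrichment(s) == pytest.approx(0.5 * 2 + 0.3 * 2)

    def test_equal_genes_double_the_single_term(self):
        s = make_summary(A_t=2, A_c=4, B_t=2, B_c=4, N_t=1, N_c=1)
        assert expected_dko_enrichment(s) == pytest.approx(2 * 0.5)

    def test_zero_denominator_names_offender(self):
        with pytest.raises(ZeroDivisionError, match="D_c"):
            observed_dko_enrichment(make_summary(D_c=0))
        with pytest.raises(ZeroDivisionError, match="N_t"):
            expected_dko_enrichment(make_summary(N_t=0))


class TestSynergyByEnrichment:
    def _null_summaries(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            ra, rb = rng.uniform(0.5, 1.5, size=2)
            out.append(
                make_summary(
                    pair=(f"A{i}", f"B{i}"),
                    A_t=ra, A_c=1, B_t=rb, B_c=1, D_t=ra * rb, D_c=1,
                )
            )
        return out

    def test_exactly_additive_pairs_yield_no_calls(self):
        summaries = []
        rng = np.random.default_rng(1)
        for i in range(20):
            ra, rb = rng.uniform(0.5, 1.5, size=2)
            summaries.append(
                make_summary(pair=(f"A{i}", f"B{i}"),
                             A_t=ra, B_t=rb, D_t=ra + rb)  # observed == expected
            )
        table, skipped = synergy_by_enrichment(summaries)
        assert not skipped
        assert not table["significant"].any()

    def test_planted_depletion_is_flagged_negative(self):
        summaries = self._null_summaries()
        null_obs = np.array([observed_dko_enrichment(s) for s in summaries])
        null_exp = np.array([expected_dko_enrichment(s) for s in summaries])
        resid_sd = np.std(null_obs - np.poly1d(np.polyfit(null_exp, null_obs, 1))(null_exp))
        target = summaries[7]
        summaries[7] = make_summary(
            pair=target.pair, A_t=target.A_t, B_t=target.B_t,
            D_t=observed_dko_enrichment(target) - 5 * resid_sd,
        )
        table, _ = synergy_by_enrichment(summaries)
        label = "A7__B7"
        assert table.loc[label, "significant"]
        assert table.loc[label, "studentized_residual"] < 0

    def test_pair_order_does_not_change_calls(self):
        summaries = self._null_summaries(seed=3)
        summaries[4] = make_summary(pair=summaries[4].pair, D_t=0.2, A_t=1, B_t=1)
        table_fwd, _ = synergy_by_enrichment(summaries)
        table_rev, _ = synergy_by_enrichment(summaries[::-1])
        sig_fwd = set(table_fwd.index[table_fwd["significant"]])
        sig_rev = set(table_rev.index[table_rev["significant"]])
        assert sig_fwd == sig_rev

    def test_zero_median_pairs_are_skipped_with_reason(self):
        summaries = self._null_summaries(seed=5)
        summaries[0] = make_summary(pair=summaries[0].pair, D_c=0)
        table, skipped = synergy_by_enrichment(summaries)
        assert "A0__B0" in skipped
        assert "A0__B0" not in table.index


class TestSynergyByRankTest:
    def _lfc_table(self, design, shift=None, seed=0, n_samples=6):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 0.3, size=(len(design), n_samples))
        lfc = pd.DataFrame(
            base, index=design.array_ids,
            columns=[f"t{i}" for i in range(n_samples)],
        )
        if shift:
            lfc.loc[shift] += -3 * 0.3
        return lfc

    def test_matched_distributions_give_no_calls(self, small_library):
        # every array carries the same per-sample LFC multiset
        row = [0.1, -0.2, 0.3, -0.4, 0.2, -0.1]
        lfc = pd.DataFrame(
            [row] * len(small_library),
            index=small_library.array_ids,
            columns=[f"t{i}" for i in range(6)],
        )
        table, _ = synergy_by_rank_test(lfc, small_library)
        assert not table["significant"].any()

    def test_planted_shift_has_smallest_adjusted_p(self, small_library):
        target = small_library.by_category("DKO")[2].array_id
        lfc = self._lfc_table(small_library, shift=target)
        table, _ = synergy_by_rank_test(lfc, small_library)
        assert table["p_adj"].idxmin() == target

    def test_rank_invariance_under_scaling(self, small_library):
        lfc = self._lfc_table(small_library, seed=9)
        t1, _ = synergy_by_rank_test(lfc, small_library)
        t2, _ = synergy_by_rank_test(2 * lfc, small_library)
        assert np.allclose(t1["p"], t2["p"])


class TestRegressionCellVsTumour:
    def test_identity_has_no_outliers(self):
        values = pd.Series(np.linspace(2, 12, 30), index=[f"e{i}" for i in range(30)])
        table = regression_cell_vs_tumour(values, values.copy())
        assert not table["significant"].any()

    def test_planted_depletion_is_flagged(self):
        rng = np.random.default_rng(2)
        cell = pd.Series(rng.uniform(4, 12, 40), index=[f"e{i}" for i in range(40)])
        tumour = cell + rng.normal(0, 0.1, 40)
        tumour.iloc[13] -= 5 * 0.1 * 10  # far below the line
        table = regression_cell_vs_tumour(cell, tumour)
        assert table.index[0] == "e13"
        assert table.loc["e13", "significant"]

    def test_affine_shift_preserves_residuals(self):
        rng = np.random.default_rng(3)
        cell = pd.Series(rng.uniform(0, 10, 25))
        tumour = cell + rng.normal(0, 0.5, 25)
        base = regression_cell_vs_tumour(cell, tumour)["studentized_residual"]
        shifted = regression_cell_vs_tumour(cell + 7, tumour + 3)["studentized_residual"]
        assert np.allclose(base.sort_index(), shifted.sort_index())


class TestInteractionModelIntegration:
    def test_planted_interaction_is_called_by_both_models(self, study_library):
        import socascreen as sc

        planted = study_library.dko_pairs()[17]
        model = sc.FitnessModel(
            fitness={g: 0.0 for g in study_library.targeting_genes()},
            interactions={planted: -2.0},
            dispersion=0.1,
            depth=1000,
        )
        screen = sc.simulate_screen(study_library, model, seed=5)
        rpm = sc.to_rpm(screen.counts)
        results = sc.InteractionModel(rpm, study_library, screen.sample_info).fit()
        label = f"{planted[0]}__{planted[1]}"
        assert label in results.significant_pairs("enrichment")
        assert label in results.significant_pairs("ranksum")
        assert results.enrichment.loc[label, "studentized_residual"] < 0
        report = sc.truth_report(screen, results.enrichment)
        assert report["sensitivity"] == 1.0
        assert "significant" in results.summary()[:100].lower() or label in results.summary()
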