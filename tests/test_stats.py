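"""Statistical battery: formula correctness against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import gammaln

from sciquant.cohort import CohortSpec, generate_cohort
from sciquant.stats import (
    ModelSpec,
    chi2_2x2,
    cochran_q,
    cohens_d,
    fisher_exact,
    friedman_kendall,
    group_summary,
    impute_group_mean,
    kendalls_w,
    mann_whitney_r,
    nested_status_matrix,
    regression_battery,
    spearman_screen,
)


class TestNestedStatusMatrix:
    def test_reconstructs_column_totals(self):
        m = nested_status_matrix(106, (45, 42, 25))
        assert m.shape == (106, 3)
        assert list(m.sum(axis=0)) == [45, 42, 25]
        # rows monotone non-increasing: nesting
        assert (np.diff(m, axis=1) <= 0).all()

    def test_non_nested_counts_raise(self):
        with pytest.raises(ValueError, match="nest"):
            nested_status_matrix(50, (10, 12, 5))


class TestCochranQ:
    def test_all_constant_rows_give_zero(self):
        m = np.ones((20, 3), dtype=int)
        rep = cochran_q(m)
        assert rep.statistic == 0.0 and rep.p == 1.0

    def test_reduces_to_uncorrected_mcnemar_at_k2(self):
        rng = np.random.default_rng(0)
        m = (rng.uniform(size=(40, 2)) < 0.4).astype(int)
        q = cochran_q(m).statistic
        b = int(((m[:, 0] == 1) & (m[:, 1] == 0)).sum())
        c = int(((m[:, 0] == 0) & (m[:, 1] == 1)).sum())
        assert q == pytest.approx((b - c) ** 2 / (b + c))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_statsmodels_on_random_matrices(self, trial):
        from statsmodels.stats.contingency_tables import cochrans_q

        rng = np.random.default_rng(trial)
        m = (rng.uniform(size=(10, 3)) < rng.uniform(0.2, 0.8)).astype(int)
        ours = cochran_q(m)
        theirs = cochrans_q(m, return_object=True)
        if np.isnan(theirs.statistic):
            assert ours.statistic == 0.0
        else:
            assert ours.statistic == pytest.approx(theirs.statistic)
            assert ours.p == pytest.approx(theirs.pvalue)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(5)
        m = (rng.uniform(size=(15, 3)) < 0.5).astype(int)
        shuffled = m[rng.permutation(15)]
        assert cochran_q(m).statistic == pytest.approx(cochran_q(shuffled).statistic)


class TestFriedmanKendall:
    def test_perfect_concordance_gives_w_one(self):
        # every subject ranks the three conditions identically, no ties
        m = np.array([[1.0, 2.0, 3.0] * 1 for _ in range(8)]) + np.arange(8)[:, None] * 10
        rep = friedman_kendall(m)
        assert rep.effect == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "q, n, expected", [(76.80, 106, 0.36), (19.50, 48, 0.20)]
    )
    def test_kendall_w_formula(self, q, n, expected):
        assert kendalls_w(q, n, 3) == pytest.approx(expected, abs=0.005)


class TestChi2:
    def test_yates_value_and_phi(self):
        rep = chi2_2x2(np.array([[45, 61], [11, 37]]))
        assert rep.statistic == pytest.approx(4.64, abs=0.005)
        assert rep.effect == pytest.approx(0.17, abs=0.005)

    def test_identical_row_proportions_give_zero(self):
        rep = chi2_2x2(np.array([[20, 40], [10, 20]]), yates=False)
        assert rep.statistic == pytest.approx(0.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2(np.array([[0, 0], [5, 7]]))


def cmle_grid_oracle(table):
    """Maximise the noncentral hypergeometric likelihood over a psi grid."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    logc = (
        gammaln(row1 + 1)
        - gammaln(support + 1)
        - gammaln(row1 - support + 1)
        + gammaln(n - row1 + 1)
        - gammaln(col1 - support + 1)
        - gammaln(n - row1 - col1 + support + 1)
    )
    from scipy.special import logsumexp

    logpsi = np.linspace(np.log(1e-3), np.log(1e3), 20001)
    weights = logc[None, :] + support[None, :] * logpsi[:, None]
    ll = logc[support == a][0] + a * logpsi - logsumexp(weights, axis=1)
    return float(np.exp(logpsi[np.argmax(ll)]))


class TestFisherExact:
    def test_conditional_mle_odds_ratio_restrictive_table(self):
        rep = fisher_exact(np.array([[25, 81], [2, 46]]))
        assert rep.effect == pytest.approx(7.03, abs=0.01)
        assert rep.p < 0.005

    def test_zero_cell_reports_unbounded_or(self):
        rep = fisher_exact(np.array([[12, 94], [0, 48]]))
        assert np.isnan(rep.effect)
        assert rep.extras["or_unbounded"]

    def test_identical_rows_give_or_one_p_one(self):
        rep = fisher_exact(np.array([[6, 9], [6, 9]]))
        assert rep.effect == pytest.approx(1.0, abs=1e-6)
        assert rep.p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[25, 81], [2, 46]],
            [[7, 3], [2, 9]],
            [[4, 12], [9, 5]],
        ],
    )
    def test_cmle_matches_likelihood_grid_search(self, table):
        rep = fisher_exact(np.array(table))
        oracle = cmle_grid_oracle(table)
        assert rep.effect == pytest.approx(oracle, rel=5e-3)


class TestMannWhitney:
    def test_complete_separation_maximises_u(self):
        x = np.arange(10, 20)
        y = np.arange(0, 8)
        rep = mann_whitney_r(x, y)
        assert rep.statistic == len(x) * len(y)

    def test_identical_distributions_give_small_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        y = rng.normal(size=4000)
        rep = mann_whitney_r(x, y)
        assert rep.effect < 0.03

    @pytest.mark.parametrize("trial", range(4))
    def test_exact_p_matches_full_permutation_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n1 = n2 = 6
        pooled = rng.permutation(np.arange(n1 + n2, dtype=float))  # tie-free
        x, y = pooled[:n1], pooled[n1:]
        rep = mann_whitney_r(x, y, method="exact")
        # enumerate all assignments of the pooled values to group 1
        u_obs = rep.statistic
        u_all = []
        for combo in itertools.combinations(range(n1 + n2), n1):
            xs = pooled[list(combo)]
            ys = np.delete(pooled, list(combo))
            u = sum((xi > ys).sum() + 0.5 * (xi == ys).sum() for xi in xs)
            u_all.append(u)
        u_all = np.asarray(u_all)
        mu = n1 * n2 / 2
        p_perm = np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-12)
        assert rep.p == pytest.approx(p_perm, abs=1e-9)


class TestSpearman:
    def test_perfectly_monotone_pair(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [2, 4, 8, 16, 32]})
        rho, _, _ = spearman_screen(df, ["a", "b"])
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_rank_formula_with_ties(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 5, size=30).astype(float)
        b = rng.integers(0, 5, size=30).astype(float)
        df = pd.DataFrame({"a": a, "b": b})
        rho, _, _ = spearman_screen(df, ["a", "b"])
        ra, rb = sps.rankdata(a), sps.rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rho.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_constant_variable_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0] * 10, "b": np.arange(10.0)})
        rho, p, sig = spearman_screen(df, ["a", "b"])
        assert np.isnan(rho.loc["a", "b"])
        assert not sig.loc["a", "b"]


class TestImputation:
    def test_missing_replaced_by_own_group_mean(self):
        df = pd.DataFrame(
            {
                "group": ["g1", "g1", "g1", "g2", "g2"],
                "v": [90.0, 100.0, np.nan, 50.0, np.nan],
            }
        )
        out, n = impute_group_mean(df, "v")
        assert n == 2
        assert out.loc[2, "v"] == pytest.approx(95.0)
        assert out.loc[4, "v"] == pytest.approx(50.0)

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"group": ["a", "b"], "v": [1.0, 2.0]})
        out, n = impute_group_mean(df, "v")
        assert n == 0
        pd.testing.assert_frame_equal(out, df)

    def test_all_missing_group_raises(self):
        df = pd.DataFrame({"group": ["a", "a"], "v": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            impute_group_mean(df, "v")


class TestGroupSummary:
    def test_cohens_d_for_reference_cognition_parameters(self):
        """IQ distributions 93.15 (13.28) vs 97.29 (11.78) give d around
        0.33 at large equal n (pooled-SD arithmetic)."""
        rng = np.random.default_rng(0)
        x = rng.normal(93.15, 13.28, size=200_000)
        y = rng.normal(97.29, 11.78, size=200_000)
        assert abs(cohens_d(x, y)) == pytest.approx(0.33, abs=0.01)

    def test_identical_groups_have_null_effects(self):
        rng = np.random.default_rng(3)
        base = generate_cohort(CohortSpec(n_sca=300, n_control=300, seed=3))
        # give both groups literally the same score vector
        shared = rng.normal(95, 12, size=300)
        for c in ("iq", "wmi", "psi"):
            base[c] = np.concatenate([shared, shared])
        base["impaired"] = (base[["iq", "wmi", "psi"]].min(axis=1) < 70).astype(int)
        out = group_summary(base)
        for var in ("iq", "wmi", "psi"):
            assert abs(out[var].effect) < 1e-9
            assert out[var].p == pytest.approx(1.0, abs=1e-9)

    def test_welch_df_closed_form(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 3, 25)
        tab = generate_cohort(CohortSpec(n_sca=40, n_control=25, seed=4))
        tab["iq"] = np.concatenate([x, y])
        out = group_summary(tab)
        v1, v2 = x.var(ddof=1) / 40, y.var(ddof=1) / 25
        nu = (v1 + v2) ** 2 / (v1**2 / 39 + v2**2 / 24)
        assert out["iq"].df == pytest.approx(nu)


class TestRegressionBattery:
    def test_forced_collinearity_triggers_documented_indicator_drop(self):
        """When the log-volume quantifier is an exact multiple of the
        presence indicator, the indicator's VIF explodes and it is
        dropped from the model."""
        tab = generate_cohort(CohortSpec(seed=9))
        tab["vol_liberal"] = np.where(tab["sci_liberal"] == 1, 10.0, 0.0)
        rep = regression_battery(tab, [ModelSpec(outcome="iq", model_id=5)])[0]
        assert rep.error is None
        assert "sci_yn" in rep.dropped
        assert "sci_log_volume" in rep.params.index

    def test_model_one_reports_lesion_indicator_with_semipartial(self):
        tab = generate_cohort(CohortSpec(seed=10))
        rep = regression_battery(tab, [ModelSpec(outcome="iq", model_id=1)])[0]
        assert rep.error is None
        assert "sci_yn" in rep.params.index
        assert "semipartial_r" in rep.params.columns
        assert rep.n == 154

    def test_interaction_models_carry_centered_group_interactions(self):
        tab = generate_cohort(CohortSpec(seed=11))
        rep = regression_battery(tab, [ModelSpec(outcome="psi", model_id=6)])[0]
        assert rep.error is None
        # the continuous quantifier's interaction always survives; the
        # presence indicator (and its interaction) may be dropped by the
        # VIF rule since presence and log-volume are strongly collinear
        assert "sci_log_volume_x_sca" in rep.params.index
        assert all(t.startswith("sci_yn") for t in rep.dropped)
        rep2 = regression_battery(tab, [ModelSpec(outcome="psi", model_id=2)])[0]
        assert "sci_yn_x_sca" in rep2.params.index

    def test_underdetermined_design_reports_error(self):
        tab = generate_cohort(CohortSpec(n_sca=4, n_control=4, seed=12))
        rep = regression_battery(tab, [ModelSpec(outcome="iq", model_id=6)])[0]
        assert rep.error is not None
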