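"""Per-eQTL factor assignment: WLS, BH, discrepancy filters, classification."""

import numpy as np
import pytest
from scipy import stats

from snspmf import (
    LdTable,
    assign_all,
    assign_factors,
    bh_adjust,
    classify_eqtls,
    filter_discrepant_factors,
    find_ubiquitous_factor,
    propagate_q_values,
    prune_perfect_ld,
    simulate_dataset,
)
from snspmf.assignment import DropReason, apply_fdr


def normal_equations_oracle(x, se, F):
    """Independent WLS solution via explicit normal equations in long double."""
    w2 = (1.0 / np.asarray(se, dtype=np.longdouble)) ** 2
    Fl = np.asarray(F, dtype=np.longdouble)
    xl = np.asarray(x, dtype=np.longdouble)
    G = Fl.T @ (w2[:, None] * Fl)
    beta = np.linalg.solve(G.astype(float), (Fl.T @ (w2 * xl)).astype(float))
    resid = xl - Fl @ beta
    dof = len(x) - F.shape[1]
    sigma2 = float((w2 * resid**2).sum()) / dof
    cov = sigma2 * np.linalg.inv(G.astype(float))
    return beta, np.sqrt(np.diag(cov)), dof


class TestAssignFactors:
    def test_exact_fit_recovers_loadings(self):
        rng = np.random.default_rng(0)
        F = np.abs(rng.standard_normal((6, 2)))
        l = np.array([1.5, -0.5])
        x = F @ l
        a = assign_factors(x, rng.uniform(0.1, 1.0, 6), F)
        assert a.coef == pytest.approx(l, abs=1e-10)

    def test_worked_t_statistic_example(self):
        # T=3, K=1, F=(1,1,1)', x=(1,2,3), se=1: coef=2, sigma2=1,
        # se(coef)=1/sqrt(3), t=2*sqrt(3), df=2, p ~ 0.0742
        a = assign_factors(np.array([1.0, 2.0, 3.0]), np.ones(3), np.ones((3, 1)))
        assert a.coef[0] == pytest.approx(2.0)
        assert a.coef_se[0] == pytest.approx(1 / np.sqrt(3))
        assert a.t_stat[0] == pytest.approx(2 * np.sqrt(3))
        assert a.df == 2
        assert a.p_value[0] == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), 2))
        assert a.p_value[0] == pytest.approx(0.0742, abs=2e-4)

    def test_doubling_se_leaves_coef_unchanged(self):
        rng = np.random.default_rng(1)
        F = np.abs(rng.standard_normal((7, 2)))
        x = rng.standard_normal(7)
        se = rng.uniform(0.2, 1.0, 7)
        a1 = assign_factors(x, se, F)
        a2 = assign_factors(x, 2 * se, F)
        assert a1.coef == pytest.approx(a2.coef, rel=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            T = int(rng.integers(4, 12))
            K = int(rng.integers(1, min(T - 1, 5) + 1))
            F = np.abs(rng.standard_normal((T, K)))
            x = rng.standard_normal(T)
            se = rng.uniform(0.1, 2.0, T)
            a = assign_factors(x, se, F)
            beta, se_beta, dof = normal_equations_oracle(x, se, F)
            assert np.max(np.abs(a.coef - beta)) < 1e-10
            assert a.coef_se == pytest.approx(se_beta, rel=1e-8)
            assert a.df == dof

    def test_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        T, K = 9, 3
        F = np.abs(rng.standard_normal((T, K)))
        x = rng.standard_normal(T)
        se = rng.uniform(0.2, 1.5, T)
        fit = sm.WLS(x, F, weights=1.0 / se**2).fit()
        a = assign_factors(x, se, F)
        assert a.coef == pytest.approx(fit.params, rel=1e-10)
        assert a.coef_se == pytest.approx(fit.bse, rel=1e-10)
        assert a.p_value == pytest.approx(fit.pvalues, rel=1e-8)

    def test_too_few_tissues_untestable(self):
        F = np.ones((3, 3))
        a = assign_factors(np.ones(3), np.ones(3), F)
        assert not a.testable
        assert all(r is DropReason.UNTESTABLE for r in a.drop_reason)

    def test_collinear_column_reported_na_others_fitted(self):
        F = np.column_stack([np.ones(6), np.ones(6), np.arange(6.0)])
        x = 2.0 * np.ones(6) + 0.5 * np.arange(6.0)
        a = assign_factors(x, np.ones(6), F)
        assert a.drop_reason[1] is DropReason.COLLINEAR_NA
        assert np.isnan(a.coef[1])
        assert a.coef[0] == pytest.approx(2.0, abs=1e-8)
        assert a.coef[2] == pytest.approx(0.5, abs=1e-8)

    def test_unobserved_tissues_excluded(self):
        F = np.abs(np.random.default_rng(5).standard_normal((6, 2)))
        x = F @ np.array([1.0, 2.0])
        x[3] = 99.0  # garbage in an unobserved slot
        obs = np.array([True, True, True, False, True, True])
        a = assign_factors(x, np.ones(6), F, observed=obs)
        assert a.coef == pytest.approx([1.0, 2.0], abs=1e-10)
        assert a.df == 5 - 2


class TestBhAdjust:
    def test_hand_computed_vectors(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_adjust([0.005, 0.05, 0.5]) == pytest.approx([0.015, 0.075, 0.5])

    def test_single_p_passes_through(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_nan_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[[0, 2]] == pytest.approx(bh_adjust([0.01, 0.04]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 50)
        expected = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)

    def test_q_at_least_p_and_bounded(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 30)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestPrunePerfectLd:
    def test_transitive_chain_one_group(self):
        ld = LdTable([("a", "b", 1.0), ("b", "c", 1.0)])
        reps, groups = prune_perfect_ld(["g1:a", "g1:b", "g1:c"], ld)
        assert reps == ["g1:a"]
        assert groups["g1:a"] == ["g1:a", "g1:b", "g1:c"]

    def test_strict_threshold(self):
        ld = LdTable([("a", "b", 0.99)])
        reps, _ = prune_perfect_ld(["g1:a", "g1:b"], ld)
        assert reps == ["g1:a", "g1:b"]

    def test_grouping_is_per_gene(self):
        ld = LdTable([("a", "b", 1.0)])
        reps, groups = prune_perfect_ld(["g1:a", "g1:b", "g2:a", "g2:b"], ld)
        assert reps == ["g1:a", "g2:a"]
        assert groups["g2:a"] == ["g2:a", "g2:b"]

    def test_no_ld_info_singletons(self):
        reps, groups = prune_perfect_ld(["g1:a", "g1:b"], LdTable())
        assert reps == ["g1:a", "g1:b"]
        assert all(len(v) == 1 for v in groups.values())


def fitted_assignment(x, se, F, fdr=0.05):
    a = assign_factors(np.asarray(x, float), np.asarray(se, float), np.asarray(F, float))
    apply_fdr([a], fdr=fdr)
    return a


class TestDiscrepancyFilters:
    def test_sign_mismatch_dropped(self):
        # factor 1's support tissues all show negative effects; a positive
        # fitted coefficient on it is a collinearity artifact
        F = np.array(
            [[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [1.0, 0.0]]
        )
        x = np.array([-1.0, -1.0, 0.5, 0.5, 0.5, 0.5])
        se = np.full(6, 0.05)
        a = fitted_assignment(x, se, F)
        a.kept = np.array([True, True])
        a.coef = np.array([0.5, 1.0])  # positive coef on factor 1, effects negative
        a.t_stat = np.array([10.0, 5.0])
        filter_discrepant_factors(a, x, se, F)
        assert not a.kept[1]
        assert a.drop_reason[1] is DropReason.SIGN_MISMATCH

    def test_same_sign_factors_not_dropped_by_opposite_rule(self):
        F = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [1.0, 1.0]])
        l = np.array([2.0, 1.5])
        x = F @ l
        se = np.full(5, 0.1)
        a = fitted_assignment(x, se, F)
        filter_discrepant_factors(a, x, se, F)
        assert a.kept.sum() == 2

    def test_opposite_small_z_dropped(self):
        # factor 1 is opposite-signed to the strongest factor and every one
        # of its support tissues has |Z| < 3: dropped
        F = np.array(
            [[1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [0.0, 0.0]]
        )
        x = np.array([5.0, 5.0, 5.0, -1.2, -2.5, 0.0])
        se = np.ones(6)
        a = fitted_assignment(x, se, F)
        a.kept = np.array([True, True])
        a.coef = np.array([5.0, -1.85])
        a.t_stat = np.array([20.0, -4.0])
        filter_discrepant_factors(a, x, se, F)
        assert not a.kept[1]
        assert a.drop_reason[1] is DropReason.OPPOSITE_SMALL_Z

    def test_opposite_large_z_kept(self):
        F = np.array(
            [[1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [0.0, 0.0]]
        )
        x = np.array([5.0, 5.0, 5.0, -3.5, -4.0, 0.0])
        se = np.ones(6)
        a = fitted_assignment(x, se, F)
        a.kept = np.array([True, True])
        a.coef = np.array([5.0, -3.75])
        a.t_stat = np.array([20.0, -8.0])
        filter_discrepant_factors(a, x, se, F)
        assert a.kept[1]

    def test_no_significant_factors_noop(self):
        F = np.ones((4, 1))
        x = np.array([0.1, -0.1, 0.05, -0.05])
        a = fitted_assignment(x, np.ones(4), F)
        filter_discrepant_factors(a, x, np.ones(4), F)
        assert not a.kept.any()


class TestClassification:
    def test_ubiquitous_factor_detection(self):
        F = np.array([[1.0, 0.5], [1.0, 0.0], [1.0, 0.7]])
        assert find_ubiquitous_factor(F) == 0
        assert find_ubiquitous_factor(np.array([[1.0, 0.0], [0.0, 1.0]])) is None

    def test_flattest_full_support_factor_wins(self):
        F = np.array([[1.0, 5.0], [1.0, 0.1], [1.0, 2.0]])
        assert find_ubiquitous_factor(F) == 0

    def test_u_and_ts_labels(self):
        F = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        x_u = F @ np.array([3.0, 0.0])
        x_both = F @ np.array([3.0, 2.0])
        se = np.full(5, 0.05)
        a_u = fitted_assignment(x_u, se, F)
        a_both = fitted_assignment(x_both, se, F)
        classify_eqtls([a_u, a_both], 0)
        assert a_u.u_eqtl and a_u.ts_factors == set()
        assert a_both.u_eqtl and a_both.ts_factors == {1}

    def test_no_factor_kept_unlabeled(self):
        F = np.ones((4, 1))
        a = fitted_assignment([0.01, -0.01, 0.02, 0.0], np.ones(4), F)
        classify_eqtls([a], 0)
        assert not a.u_eqtl and a.ts_factors == set()

    def test_no_full_support_factor_warns(self):
        F = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        a = fitted_assignment(F @ np.array([2.0, 2.0]), np.full(5, 0.1), F)
        with pytest.warns(UserWarning, match="full tissue support"):
            classify_eqtls([a], find_ubiquitous_factor(F))
        assert not a.u_eqtl


class TestPropagation:
    def test_group_members_inherit(self):
        F = np.ones((4, 1))
        a = fitted_assignment([1.0, 1.1, 0.9, 1.0], np.full(4, 0.1), F)
        a.eqtl_id = "g1:a"
        out = propagate_q_values({"g1:a": ["g1:a", "g1:b", "g1:c"]}, [a])
        assert [o.eqtl_id for o in out] == ["g1:a", "g1:b", "g1:c"]
        for o in out[1:]:
            assert o.q_value == pytest.approx(a.q_value)
            assert np.array_equal(o.kept, a.kept)

    def test_identity_on_singletons(self):
        F = np.ones((4, 1))
        a = fitted_assignment([1.0, 1.1, 0.9, 1.0], np.full(4, 0.1), F)
        a.eqtl_id = "g1:a"
        out = propagate_q_values({"g1:a": ["g1:a"]}, [a])
        assert out == [a]


class TestEndToEndRecovery:
    def test_sign_and_support_recovery_with_true_factors(self):
        # low noise + the true F: detectable active loadings (those not
        # buried under the coefficient noise floor ~ sigma/sqrt(sum F^2),
        # here |l| >= 0.1 vs noise sd ~ 0.02) come back significant with the
        # right sign at >= 90%, and significant calls are overwhelmingly
        # truly active. Standard-normal loadings near zero are undetectable
        # at any FDR, so the unconditional recall sits a few points lower.
        eff, truth = simulate_dataset(N=100, T=10, K=5, sigma2=0.001, seed=11)
        assignments = assign_all(eff, truth.F_true, fdr=0.05)
        kept = np.array([a.kept for a in assignments])
        sign_ok = np.array(
            [np.sign(a.coef) == np.sign(truth.L_true[i]) for i, a in enumerate(assignments)]
        )
        active = truth.L_true != 0
        detectable = active & (np.abs(truth.L_true) >= 0.1)
        recall = (kept & sign_ok & detectable).sum() / detectable.sum()
        precision = (kept & active).sum() / kept.sum()
        assert recall >= 0.9
        assert precision >= 0.9

    def test_filtering_never_creates_significance(self):
        eff, truth = simulate_dataset(N=50, T=10, K=5, sigma2=0.01, seed=12)
        assignments = assign_all(eff, truth.F_true, fdr=0.05)
        for a in assignments:
            if a.testable:
                assert np.all(a.q_value[a.kept] < 0.05)
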