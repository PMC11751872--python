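import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpmeta import (EffectEstimate, GeneticModel, SimConfig, bias_tests,
                     choose_and_pool, leave_one_out, meta_regression,
                     pool_fixed, pool_random, simulate_corpus, study_effect,
                     subgroup_analysis)
from snpmeta.errors import InsufficientStudiesError
from snpmeta.pairwise import begg_test, egger_test


def eff(y, se, label=""):
    return EffectEstimate(log_or=y, se=se, label=label)


class TestFixedEffect:
    def test_identical_studies(self):
        res = pool_fixed([eff(0.5, 0.2), eff(0.5, 0.2)])
        assert res.effect.log_or == pytest.approx(0.5)
        assert res.effect.se == pytest.approx(0.2 / math.sqrt(2))
        assert res.het.q == pytest.approx(0.0, abs=1e-12)
        assert res.het.i2 == 0.0

    def test_equal_weights_give_plain_mean(self):
        res = pool_fixed([eff(0.0, 0.3), eff(0.6931, 0.3)])
        assert res.effect.log_or == pytest.approx(0.34655, abs=1e-4)
        # Q at equal weights: 2 * (0.34655 / 0.3)^2... hand value
        assert res.het.q == pytest.approx(2 * (0.34655 / 0.3) ** 2,
                                          rel=1e-3)

    def test_single_study_is_an_error(self):
        with pytest.raises(InsufficientStudiesError):
            pool_fixed([eff(0.5, 0.2)])


class TestRandomEffects:
    def test_homogeneous_collapses_to_fixed(self):
        effects = [eff(0.5, 0.2), eff(0.5, 0.2), eff(0.5, 0.2)]
        rand, fixed = pool_random(effects), pool_fixed(effects)
        assert rand.het.tau2 == 0.0
        assert rand.effect.log_or == pytest.approx(fixed.effect.log_or)
        assert rand.effect.se == pytest.approx(fixed.effect.se)

    def test_dersimonian_laird_moment_estimate(self):
        # w = 100 each; Q = 50, df = 1, C = 200 - 100 = 100
        res = pool_random([eff(0.0, 0.1), eff(1.0, 0.1)])
        assert res.het.q == pytest.approx(50.0)
        assert res.het.tau2 == pytest.approx((50 - 1) / 100)
        assert res.effect.se > pool_fixed(
            [eff(0.0, 0.1), eff(1.0, 0.1)]).effect.se

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 1.0)),
                    min_size=2, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_random_se_never_below_fixed(self, pairs):
        effects = [eff(y, s) for y, s in pairs]
        assert (pool_random(effects).effect.se
                >= pool_fixed(effects).effect.se - 1e-12)

    @given(st.permutations(range(5)))
    @settings(max_examples=30, deadline=None)
    def test_pooling_is_permutation_invariant(self, order):
        base = [eff(0.1 * i, 0.1 + 0.05 * i) for i in range(5)]
        shuffled = [base[i] for i in order]
        a, b = pool_random(base), pool_random(shuffled)
        assert a.effect.log_or == pytest.approx(b.effect.log_or, abs=1e-12)
        assert a.het.tau2 == pytest.approx(b.het.tau2, abs=1e-12)


class TestSwitchingRule:
    def test_homogeneous_uses_fixed(self):
        res = choose_and_pool([eff(0.5, 0.2), eff(0.5, 0.2)])
        assert res.method == "fixed"

    def test_heterogeneous_uses_random(self):
        res = choose_and_pool([eff(0.0, 0.1), eff(1.0, 0.1)])
        assert res.method == "random"

    def test_boundary_i2_of_exactly_50_goes_random(self):
        # k=2, equal se 0.1: Q = w*delta^2/2 = 2 at delta = 0.2, so
        # I^2 = 50 exactly while p_Q = 0.157 > 0.1 -> random (strict <)
        res = choose_and_pool([eff(0.0, 0.1), eff(0.2, 0.1)])
        assert res.het.i2 == pytest.approx(50.0, abs=1e-9)
        assert res.het.p_q > 0.1
        assert res.method == "random"


class TestLeaveOneOut:
    def test_identical_studies_symmetric(self):
        effects = [eff(0.4, 0.2, str(i)) for i in range(3)]
        results = leave_one_out(effects)
        assert len(results) == 3
        assert all(r.effect.log_or == pytest.approx(0.4) for r in results)

    def test_outlier_removal_minimizes_i2(self):
        effects = [eff(0.4, 0.1, "a"), eff(0.45, 0.1, "b"),
                   eff(2.0, 0.1, "outlier")]
        results = leave_one_out(effects)
        i2s = [r.het.i2 for r in results]
        assert min(i2s) == i2s[2]  # excluding the outlier

    def test_two_studies_is_an_error(self):
        with pytest.raises(InsufficientStudiesError):
            leave_one_out([eff(0.4, 0.2), eff(0.4, 0.2)])


class TestSubgroups:
    def test_equal_strata_show_no_difference(self):
        effects = [eff(0.5, 0.2)] * 4
        labels = ["A", "A", "B", "B"]
        res = subgroup_analysis(effects, labels)
        assert res.q_between == pytest.approx(0.0, abs=1e-12)
        assert res.p_between == pytest.approx(1.0)

    def test_separated_strata_detected(self):
        effects = [eff(0.0, 0.05)] * 3 + [eff(1.0, 0.05)] * 3
        labels = ["A"] * 3 + ["B"] * 3
        res = subgroup_analysis(effects, labels)
        assert res.p_between < 0.05

    def test_singleton_stratum_descriptive_only(self):
        effects = [eff(0.5, 0.2), eff(0.5, 0.2), eff(0.9, 0.2)]
        res = subgroup_analysis(effects, ["A", "A", "B"])
        assert res.descriptive_only == ["B"]
        assert res.q_between is None


class TestMetaRegression:
    def test_constant_covariate_is_an_error(self):
        effects = [eff(0.1 * i, 0.1) for i in range(5)]
        with pytest.raises(ValueError):
            meta_regression(effects, ["x"] * 5)

    def test_null_moderator_coefficient_near_zero(self):
        effects = [eff(0.5, 0.1)] * 3 + [eff(0.5, 0.1)] * 3
        res = meta_regression(effects, ["A"] * 3 + ["B"] * 3)
        assert res.coefficients[1] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_simulated_moderator_shift(self):
        rng = np.random.default_rng(7)
        labels = ["A"] * 10 + ["B"] * 10
        shift = {"A": 0.0, "B": 0.5}
        effects = [eff(rng.normal(0.2 + shift[lab], 0.1), 0.1)
                   for lab in labels]
        res = meta_regression(effects, labels)
        assert res.coefficients[1] == pytest.approx(0.5, abs=0.15)


class TestPublicationBias:
    def test_symmetric_funnel_has_null_egger_intercept(self):
        ses = np.linspace(0.1, 0.5, 6)
        effects = ([eff(0.3 * s / 0.5, s) for s in ses]
                   + [eff(-0.3 * s / 0.5, s) for s in ses])
        intercept, p = egger_test(effects)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_begg_tau_matches_enumeration_oracle(self):
        # effects rising with rising variance -> perfect concordance
        ys = np.linspace(-1.0, 1.0, 12)
        ses = np.linspace(0.1, 0.5, 12)
        effects = [eff(y, s) for y, s in zip(ys, ses)]
        tau, p = begg_test(effects)

        # independent oracle: concordant/discordant pair counting on the
        # standardized deviates vs variances
        w = 1.0 / ses ** 2
        ybar = np.sum(w * ys) / np.sum(w)
        dev = (ys - ybar) / np.sqrt(ses ** 2 - 1.0 / np.sum(w))
        var = ses ** 2
        conc = disc = 0
        for i in range(12):
            for j in range(i + 1, 12):
                s = np.sign(dev[i] - dev[j]) * np.sign(var[i] - var[j])
                conc += s > 0
                disc += s < 0
        expected = (conc - disc) / (12 * 11 / 2)
        assert tau == pytest.approx(expected, abs=1e-12)
        assert tau == pytest.approx(1.0)

    def test_fewer_than_ten_studies_not_applicable(self):
        effects = [eff(0.1 * i, 0.1 + 0.02 * i, str(i)) for i in range(9)]
        res = bias_tests(effects)
        assert not res.applicable
        assert res.egger_p is None and res.begg_p is None

    def test_ten_studies_reports_both_tests(self):
        effects = [eff(0.1 * i, 0.1 + 0.02 * i, str(i)) for i in range(10)]
        res = bias_tests(effects)
        assert res.applicable
        assert 0 <= res.egger_p <= 1 and 0 <= res.begg_p <= 1


def test_pooling_agrees_with_statsmodels_reference():
    """Dual-route check of fixed and DL pooling against statsmodels."""
    from statsmodels.stats.meta_analysis import combine_effects

    ys = np.array([0.12, 0.55, -0.08, 0.30, 0.71])
    ses = np.array([0.15, 0.22, 0.18, 0.30, 0.12])
    effects = [eff(y, s) for y, s in zip(ys, ses)]
    ref = combine_effects(ys, ses ** 2, method_re="dl")

    fixed = pool_fixed(effects)
    rand = pool_random(effects)
    assert fixed.effect.log_or == pytest.approx(ref.mean_effect_fe,
                                                abs=1e-10)
    assert rand.effect.log_or == pytest.approx(ref.mean_effect_re,
                                               abs=1e-10)
    assert rand.het.tau2 == pytest.approx(ref.tau2, abs=1e-10)
    assert fixed.effect.se == pytest.approx(ref.sd_eff_w_fe, abs=1e-10)


def test_ci_coverage_in_homogeneous_meta_analyses():
    """95% CI of choose_and_pool covers a true OR of 1.5 in 90-98% of
    homogeneous replicates (k = 10 studies of 1000+1000 subjects)."""
    covered = 0
    n_rep = 500
    for rep in range(n_rep):
        cfg = SimConfig(k_studies=10, n_cases=1000, n_controls=1000,
                        maf=0.3, true_model=GeneticModel.RECESSIVE,
                        true_or=1.5, tau=0.0, seed=20_000 + rep)
        studies, _ = simulate_corpus(cfg)
        effects = [study_effect(s, GeneticModel.RECESSIVE) for s in studies]
        pooled = choose_and_pool(effects)
        covered += pooled.effect.ci_low <= 1.5 <= pooled.effect.ci_high
    assert 0.90 <= covered / n_rep <= 0.98
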