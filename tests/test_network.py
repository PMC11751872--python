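import math

import numpy as np
import pytest

from snpmeta import GeneticModel, NmaConfig, psrf, sucra
from snpmeta.errors import ConvergenceError, InsufficientStudiesError
from snpmeta.network import (NmaPosterior, derive_model_contrasts, fit_nma,
                             rank_models, rank_probabilities,
                             ranking_criterion)


def make_posterior(d_het, d_hom):
    d_het = np.asarray(d_het, dtype=float)
    d_hom = np.asarray(d_hom, dtype=float)
    return NmaPosterior(d_het=d_het, d_hom=d_hom,
                        tau=np.zeros_like(d_het),
                        baseline_logit=np.zeros_like(d_het),
                        psrf={}, per_chain={})


class TestPsrf:
    def test_identical_constant_chains_return_one(self):
        chains = np.ones((3, 50))
        assert psrf(chains) == 1.0

    def test_constant_but_unequal_chains_error(self):
        chains = np.vstack([np.zeros(50), np.ones(50)])
        with pytest.raises(ConvergenceError):
            psrf(chains)

    def test_same_distribution_converges(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 5000))
        assert psrf(chains) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 1000))
        chains[1] += 10.0
        assert psrf(chains) > 1.1

    def test_matches_hand_formula(self):
        chains = np.array([[1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10],
                           [2.0, 3, 4, 5, 6, 7, 8, 9, 10, 11]])
        m, n = chains.shape
        w = chains.var(axis=1, ddof=1).mean()
        b = n * np.var(chains.mean(axis=1), ddof=1)
        expected = math.sqrt(((n - 1) / n * w + b / n) / w)
        assert psrf(chains) == pytest.approx(expected, abs=1e-12)


class TestSucra:
    def test_sure_winner_and_loser(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert sucra(probs) == pytest.approx([1.0, 0.0])

    def test_uniform_rank_matrix_is_half(self):
        for k in (2, 4, 6):
            probs = np.full((k, k), 1.0 / k)
            assert sucra(probs) == pytest.approx([0.5] * k)

    def test_cumulative_sum_arithmetic(self):
        # model 1 cumulative rank probabilities (0.5, 0.8) -> 0.65
        probs = np.array([[0.5, 0.3, 0.2],
                          [0.3, 0.4, 0.3],
                          [0.2, 0.3, 0.5]])
        scores = sucra(probs)
        assert scores[0] == pytest.approx(0.65)

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sucra(np.array([[0.7, 0.2], [0.5, 0.5]]))

    def test_mean_sucra_is_exactly_half_for_rank_matrices(self):
        rng = np.random.default_rng(3)
        draws = {m: rng.standard_normal(400) for m in GeneticModel}
        _models, probs = rank_probabilities(draws)
        assert sucra(probs).mean() == pytest.approx(0.5, abs=1e-12)


class TestDeriveContrasts:
    def test_null_draws_propagate_to_all_models(self):
        post = make_posterior([0.0, 0.0], [0.0, 0.0])
        out = derive_model_contrasts(post, (0.49, 0.42, 0.09))
        assert set(out) == set(GeneticModel)
        for draws in out.values():
            assert draws == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_mixture_construction_hand_values(self):
        post = make_posterior([0.0], [math.log(2)])
        out = derive_model_contrasts(post, (0.49, 0.42, 0.09))
        assert out[GeneticModel.RECESSIVE][0] == pytest.approx(math.log(2))
        assert out[GeneticModel.DOMINANT][0] == pytest.approx(
            math.log((0.42 + 0.18) / 0.51), abs=1e-12)
        assert out[GeneticModel.HOMOZYGOTE][0] == pytest.approx(math.log(2))

    def test_homozygote_draws_are_identically_d_hom(self):
        rng = np.random.default_rng(5)
        post = make_posterior(rng.standard_normal(100),
                              rng.standard_normal(100))
        out = derive_model_contrasts(post, (0.5, 0.3, 0.2))
        np.testing.assert_array_equal(out[GeneticModel.HOMOZYGOTE],
                                      post.d_hom)
        np.testing.assert_array_equal(out[GeneticModel.HETEROZYGOTE],
                                      post.d_het)

    def test_degenerate_mix_skips_affected_models(self):
        post = make_posterior([0.1], [0.2])
        out = derive_model_contrasts(post, (0.5, 0.5, 0.0))
        assert GeneticModel.HETEROZYGOTE in out
        assert GeneticModel.RECESSIVE not in out
        assert any("degenerate" in w for w in post.warnings)


def _simulate_network(rng, k, n_per_arm, d_het, d_hom, tau=0.0):
    events = np.empty((k, 3))
    trials = np.full((k, 3), float(n_per_arm))
    for i in range(k):
        mu = rng.normal(-0.5, 0.3)
        for g, d in enumerate((0.0, d_het, d_hom)):
            delta = rng.normal(d, tau) if g else 0.0
            p = 1.0 / (1.0 + math.exp(-(mu + delta)))
            events[i, g] = rng.binomial(n_per_arm, p)
    return events, trials


class TestFitNma:
    def test_single_chain_is_an_error(self):
        with pytest.raises(ConvergenceError):
            NmaConfig(chains=1)

    def test_one_study_is_an_error(self):
        with pytest.raises(InsufficientStudiesError):
            fit_nma(np.array([[5, 5, 5.]]), np.array([[10, 10, 10.]]),
                    NmaConfig(chains=2, burn_in=10, iterations=20, seed=0))

    def test_recovers_known_homozygote_effect(self):
        rng = np.random.default_rng(11)
        events, trials = _simulate_network(rng, k=6, n_per_arm=1000,
                                           d_het=0.0, d_hom=math.log(2))
        post = fit_nma(events, trials,
                       NmaConfig(chains=2, burn_in=1500, iterations=2500,
                                 seed=2))
        assert post.d_hom.mean() == pytest.approx(math.log(2), abs=0.15)
        assert post.d_het.mean() == pytest.approx(0.0, abs=0.15)
        assert max(post.psrf.values()) < 1.1

    def test_null_network_concentrates_at_zero(self):
        events = np.tile([40.0, 40.0, 40.0], (4, 1))
        trials = np.full((4, 3), 100.0)
        post = fit_nma(events, trials,
                       NmaConfig(chains=2, burn_in=1000, iterations=2000,
                                 seed=3))
        assert abs(post.d_het.mean()) < 0.15
        assert abs(post.d_hom.mean()) < 0.15

    def test_seeded_reproducibility(self):
        events = np.array([[30, 45, 12.], [25, 50, 15.]])
        trials = np.full((2, 3), 100.0)
        cfg = NmaConfig(chains=2, burn_in=200, iterations=300, seed=9)
        a = fit_nma(events, trials, cfg)
        b = fit_nma(events, trials, cfg)
        np.testing.assert_array_equal(a.d_hom, b.d_hom)
        np.testing.assert_array_equal(a.tau, b.tau)

    def test_agrees_with_pairwise_in_homogeneous_limit(self):
        """With identical studies and no heterogeneity the derived
        recessive contrast matches the pairwise table log-OR."""
        from snpmeta import build_contrast, estimate_or

        case = (449, 385, 166)   # recessive OR 2 vs HWE(0.3) controls
        ctrl = (490, 420, 90)
        events = np.tile(np.array(case, dtype=float), (3, 1))
        trials = np.array(case, dtype=float) + np.array(ctrl, dtype=float)
        trials = np.tile(trials, (3, 1))
        post = fit_nma(events, trials,
                       NmaConfig(chains=2, burn_in=1500, iterations=2500,
                                 seed=4))
        out = derive_model_contrasts(post, np.array(ctrl, dtype=float))
        pairwise = estimate_or(build_contrast(case, ctrl,
                                              GeneticModel.RECESSIVE))
        assert out[GeneticModel.RECESSIVE].mean() == pytest.approx(
            pairwise.log_or, abs=0.1)


def test_information_weighted_ranking_prefers_whole_sample_model():
    """Recessive and homozygote contrasts tie in |log-OR| under a pure
    recessive effect; the information-weighted criterion breaks the tie
    toward the dichotomization that uses every subject."""
    post = make_posterior(np.zeros(200), np.full(200, math.log(2)))
    mix = (0.49, 0.42, 0.09)
    contrasts = derive_model_contrasts(post, mix)
    scores = ranking_criterion(post, mix, contrasts, criterion="z")
    assert np.all(scores[GeneticModel.RECESSIVE]
                  > scores[GeneticModel.HOMOZYGOTE])
    abs_scores = ranking_criterion(post, mix, contrasts,
                                   criterion="abs_logor")
    assert abs_scores[GeneticModel.RECESSIVE] == pytest.approx(
        abs_scores[GeneticModel.HOMOZYGOTE])
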