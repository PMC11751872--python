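"""Bayesian network meta-analysis over genotype nodes, with SUCRA ranking.

Per SNP, every study contributes three arms (genotypes 11, 12, 22) with a
binomial case-membership outcome: events = cases with that genotype,
trials = all subjects carrying it.  The hierarchical logistic model is

    y_ig ~ Binomial(n_ig, p_ig),  logit(p_ig) = mu_i + delta_ig,
    delta_i,11 = 0,   delta_ig ~ Normal(d_g, tau^2)  for g in {12, 22},

with d_11 = 0, vague Normal(0, 10^2) priors on the study baselines mu_i
and the basic parameters d_12, d_22, and a half-Normal(0, 1) prior on the
between-study SD tau.  Sampling is a seeded Metropolis-within-Gibbs
scheme (vectorized random-walk updates for mu and delta, conjugate Gibbs
for d, log-scale random walk for tau) with step sizes adapted during
burn-in.  Convergence is gated on the Gelman-Rubin potential scale
reduction factor; PSRF above 1.1 on any basic parameter attaches a
warning to the posterior.

The six genetic-model contrasts are derived per posterior draw from the
basic parameters and the pooled control genotype mix, and ranked per
draw by direction-agnostic information-weighted association strength
(|log-OR| over the dichotomization's unit-information Woolf SE; see
``ranking_criterion``); SUCRA summarizes the rank distribution per
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .contrasts import GeneticModel
from .errors import ConvergenceError, InsufficientStudiesError

PSRF_WARN = 1.1
_PRIOR_SD_MU = 10.0
_PRIOR_SD_D = 10.0
_PRIOR_SCALE_TAU = 1.0


@dataclass(frozen=True)
class NmaConfig:
    """MCMC settings; the defaults are 4 chains, 20,000 burn-in and
    50,000 retained iterations per chain."""

    chains: int = 4
    burn_in: int = 20000
    iterations: int = 50000
    seed: int = 0
    thin: int = 1

    def __post_init__(self):
        if self.chains < 2:
            raise ConvergenceError(
                "PSRF requires at least 2 chains; got "
                f"{self.chains}")
        if self.iterations <= 0 or self.burn_in < 0:
            raise ValueError("iterations must be positive, burn_in >= 0")


@dataclass
class NmaPosterior:
    """Posterior draws of the basic parameters, pooled across chains."""

    d_het: np.ndarray        # d_12, (total draws,)
    d_hom: np.ndarray        # d_22
    tau: np.ndarray
    baseline_logit: np.ndarray   # mean study baseline per draw
    psrf: dict               # parameter name -> PSRF
    per_chain: dict          # parameter name -> (chains, draws) array
    warnings: list = field(default_factory=list)
    dropped_nodes: list = field(default_factory=list)


def arm_counts(studies) -> tuple[np.ndarray, np.ndarray]:
    """Events/trials arrays (k, 3) for one SNP's GenotypeStudy records."""
    events = np.array([s.case_counts for s in studies], dtype=float)
    totals = np.array(
        [[c + t for c, t in zip(s.case_counts, s.control_counts)]
         for s in studies], dtype=float)
    return events, totals


def _binom_loglik(eta, y, n, mask):
    """Sum over arms of y*eta - n*log(1 + exp(eta)), masked."""
    return np.where(mask, y * eta - n * np.logaddexp(0.0, eta), 0.0)


def _run_chain(y, n, mask, n_iter, burn_in, rng, thin=1):
    k = y.shape[0]
    mu = np.zeros(k)
    delta = np.zeros((k, 2))
    d = np.zeros(2)
    tau = 0.5

    step_mu = np.full(k, 0.3)
    step_delta = np.full((k, 2), 0.3)
    step_tau = 0.5
    acc_mu = np.zeros(k)
    acc_delta = np.zeros((k, 2))
    acc_tau = 0.0
    window = 50

    n_keep = (n_iter + thin - 1) // thin
    out_d = np.empty((n_keep, 2))
    out_tau = np.empty(n_keep)
    out_mu = np.empty(n_keep)

    def arm_ll(mu_, delta_):
        eta = mu_[:, None] + np.concatenate(
            [np.zeros((k, 1)), delta_], axis=1)
        return _binom_loglik(eta, y, n, mask)

    ll = arm_ll(mu, delta)  # (k, 3)
    kept = 0
    total = burn_in + n_iter
    for it in range(total):
        # --- mu: vectorized random-walk MH, one proposal per study -----
        prop = mu + step_mu * rng.standard_normal(k)
        ll_prop = arm_ll(prop, delta)
        log_r = (ll_prop.sum(axis=1) - ll.sum(axis=1)
                 + (mu ** 2 - prop ** 2) / (2 * _PRIOR_SD_MU ** 2))
        accept = np.log(rng.random(k)) < log_r
        mu = np.where(accept, prop, mu)
        ll = np.where(accept[:, None], ll_prop, ll)
        acc_mu += accept

        # --- delta: all 2k arm effects are conditionally independent ---
        prop_d = delta + step_delta * rng.standard_normal((k, 2))
        ll_prop = arm_ll(mu, prop_d)
        prior_cur = (delta - d[None, :]) ** 2
        prior_prop = (prop_d - d[None, :]) ** 2
        log_r = (ll_prop[:, 1:] - ll[:, 1:]
                 + (prior_cur - prior_prop) / (2 * tau ** 2))
        accept = np.log(rng.random((k, 2))) < log_r
        delta = np.where(accept, prop_d, delta)
        ll[:, 1:] = np.where(accept, ll_prop[:, 1:], ll[:, 1:])
        acc_delta += accept

        # --- d: conjugate normal given delta and tau --------------------
        prec = k / tau ** 2 + 1.0 / _PRIOR_SD_D ** 2
        mean = (delta.sum(axis=0) / tau ** 2) / prec
        d = mean + rng.standard_normal(2) / math.sqrt(prec)

        # --- tau: random walk on log tau, half-normal prior -------------
        log_tau_prop = math.log(tau) + step_tau * rng.standard_normal()
        tau_prop = math.exp(log_tau_prop)
        resid = ((delta - d[None, :]) ** 2).sum()
        def tau_logpost(t):
            return (-2 * k * math.log(t) - resid / (2 * t ** 2)
                    - t ** 2 / (2 * _PRIOR_SCALE_TAU ** 2) + math.log(t))
        if math.log(rng.random()) < tau_logpost(tau_prop) - tau_logpost(tau):
            tau = tau_prop
            acc_tau += 1

        # --- burn-in step-size adaptation -------------------------------
        if it < burn_in and (it + 1) % window == 0:
            step_mu *= np.exp((acc_mu / window - 0.44))
            step_delta *= np.exp((acc_delta / window - 0.44))
            step_tau *= math.exp(acc_tau / window - 0.44)
            acc_mu[:] = 0.0
            acc_delta[:] = 0.0
            acc_tau = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_d[kept] = d
            out_tau[kept] = tau
            out_mu[kept] = mu.mean()
            kept += 1

    return out_d[:kept], out_tau[:kept], out_mu[:kept]


def fit_nma(events: np.ndarray, trials: np.ndarray,
            config: NmaConfig = NmaConfig()) -> NmaPosterior:
    """Fit the three-node hierarchical logistic NMA for one SNP.

    Parameters
    ----------
    events, trials : (k, 3) arrays over studies x genotypes (11, 12, 22);
        events are cases carrying the genotype, trials all subjects
        carrying it.  Arms with zero trials in a study are skipped; a
        genotype with zero trials in *every* study is dropped as a node.
    """
    events = np.asarray(events, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if events.ndim != 2 or events.shape[1] != 3 or events.shape != trials.shape:
        raise ValueError("events and trials must both be (k, 3) arrays")
    if events.shape[0] < 2:
        raise InsufficientStudiesError(
            "network meta-analysis requires at least 2 studies")
    if np.any(events > trials) or np.any(events < 0):
        raise ValueError("events must satisfy 0 <= events <= trials")

    mask = trials > 0
    dropped = [g for j, g in enumerate(("11", "12", "22"))
               if not mask[:, j].any()]
    warnings = []
    if dropped:
        warnings.append(f"genotype nodes absent from all studies: {dropped}")

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains_d = []
    chains_tau = []
    chains_mu = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        d, tau, mu = _run_chain(events, trials, mask, config.iterations,
                                config.burn_in, rng, thin=config.thin)
        chains_d.append(d)
        chains_tau.append(tau)
        chains_mu.append(mu)

    per_chain = {
        "d_het": np.stack([c[:, 0] for c in chains_d]),
        "d_hom": np.stack([c[:, 1] for c in chains_d]),
        "tau": np.stack(chains_tau),
    }
    psrf_map = {name: psrf(draws) for name, draws in per_chain.items()}
    bad = {name: r for name, r in psrf_map.items() if r > PSRF_WARN}
    if bad:
        warnings.append(f"PSRF above {PSRF_WARN}: "
                        + ", ".join(f"{k}={v:.3f}" for k, v in bad.items()))

    return NmaPosterior(
        d_het=per_chain["d_het"].ravel(),
        d_hom=per_chain["d_hom"].ravel(),
        tau=per_chain["tau"].ravel(),
        baseline_logit=np.concatenate(chains_mu),
        psrf=psrf_map,
        per_chain=per_chain,
        warnings=warnings,
        dropped_nodes=dropped,
    )


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    chains : (m, n) array of m >= 2 chains of equal length n >= 10.
    Returns sqrt(((n-1)/n * W + B/n) / W).  Identical constant chains
    return 1.0 by convention; constant but unequal chains are an error.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("psrf needs >= 2 chains of equal length >= 10")
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = float(chains.var(axis=1, ddof=1).mean())
    b = n * float(np.var(means, ddof=1))
    if w == 0.0:
        if b == 0.0:
            return 1.0
        raise ConvergenceError(
            "zero within-chain variance with differing chain means")
    return float(math.sqrt(((n - 1) / n * w + b / n) / w))


def derive_model_contrasts(post: NmaPosterior,
                           control_mix: Sequence[float]
                           ) -> dict[GeneticModel, np.ndarray]:
    """Per-draw log-ORs of the six genetic models.

    The homozygote and heterozygote contrasts are the basic parameters
    themselves.  The composite models are derived by tilting the pooled
    control genotype mix: per draw the implied case genotype distribution
    has odds proportional to control probabilities x exp(d_g); the
    composite grouping's log-OR follows from the two distributions.
    Models whose groupings involve a zero control-mix component are
    skipped with a warning recorded on the posterior.
    """
    p = np.asarray(control_mix, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or p.sum() <= 0:
        raise ValueError("control_mix must be a non-negative triple")
    p = p / p.sum()
    dh, dH = post.d_het, post.d_hom
    q0 = p[0] * np.ones_like(dh)
    q1 = p[1] * np.exp(dh)
    q2 = p[2] * np.exp(dH)

    out: dict[GeneticModel, np.ndarray] = {
        GeneticModel.HETEROZYGOTE: dh.copy(),
        GeneticModel.HOMOZYGOTE: dH.copy(),
    }

    def _safe(model, numer_q, denom_q, numer_p, denom_p):
        if numer_p <= 0 or denom_p <= 0:
            post.warnings.append(
                f"model {model.value} skipped: degenerate control mix")
            return
        out[model] = np.log((numer_q / denom_q) / (numer_p / denom_p))

    _safe(GeneticModel.DOMINANT, q1 + q2, q0, p[1] + p[2], p[0])
    _safe(GeneticModel.RECESSIVE, q2, q0 + q1, p[2], p[0] + p[1])
    _safe(GeneticModel.OVERDOMINANT, q1, q0 + q2, p[1], p[0] + p[2])
    # allelic: variant-allele odds in the implied case mix vs controls
    tot_q = q0 + q1 + q2
    fq = (0.5 * q1 + q2) / tot_q
    fp = 0.5 * p[1] + p[2]
    if fp <= 0 or fp >= 1:
        post.warnings.append("model allelic skipped: degenerate control mix")
    else:
        out[GeneticModel.ALLELIC] = np.log(
            (fq / (1 - fq)) / (fp / (1 - fp)))
    return out


def _unit_se(model: GeneticModel, mix: np.ndarray) -> np.ndarray:
    """Woolf SE of the model's 2x2 per unit of per-group sample size.

    mix : (n_draws, 3) genotype probability rows (or a single row for
    controls).  Measures how precisely the dichotomized contrast can be
    estimated in a population with that genotype mix; models that discard
    subjects (homozygote, heterozygote) or split off tiny groups carry
    larger unit SEs.  Allelic cells are allele counts, hence the /2.
    """
    p0, p1, p2 = mix[..., 0], mix[..., 1], mix[..., 2]
    if model is GeneticModel.DOMINANT:
        return 1.0 / (p1 + p2) + 1.0 / p0
    if model is GeneticModel.RECESSIVE:
        return 1.0 / p2 + 1.0 / (p0 + p1)
    if model is GeneticModel.OVERDOMINANT:
        return 1.0 / p1 + 1.0 / (p0 + p2)
    if model is GeneticModel.HOMOZYGOTE:
        return 1.0 / p2 + 1.0 / p0
    if model is GeneticModel.HETEROZYGOTE:
        return 1.0 / p1 + 1.0 / p0
    if model is GeneticModel.ALLELIC:
        f = 0.5 * p1 + p2
        return (1.0 / f + 1.0 / (1.0 - f)) / 2.0
    raise ValueError(model)


def ranking_criterion(post: NmaPosterior,
                      control_mix: Sequence[float],
                      contrasts: dict[GeneticModel, np.ndarray],
                      criterion: str = "z"
                      ) -> dict[GeneticModel, np.ndarray]:
    """Per-draw ranking scores for the candidate genetic models.

    criterion="z" (default): |log-OR| divided by the unit-information
    Woolf SE of the model's implied 2x2 (control mix for the control
    group, draw-specific implied case mix for cases, equal group sizes).
    Suitability for risk prediction then reflects both association
    strength and how precisely the dichotomization can measure it; this
    also resolves the exact ties between nested dichotomizations (e.g.
    recessive vs homozygote under a purely recessive effect) that plain
    |log-OR| cannot.

    criterion="abs_logor": direction-agnostic association strength only.
    """
    if criterion == "abs_logor":
        return {m: np.abs(d) for m, d in contrasts.items()}
    if criterion != "z":
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    p = np.asarray(control_mix, dtype=float)
    p = p / p.sum()
    q = np.stack([p[0] * np.ones_like(post.d_het),
                  p[1] * np.exp(post.d_het),
                  p[2] * np.exp(post.d_hom)], axis=-1)
    q = q / q.sum(axis=-1, keepdims=True)
    scores = {}
    for m, d in contrasts.items():
        var = _unit_se(m, q) + _unit_se(m, p)
        scores[m] = np.abs(d) / np.sqrt(var)
    return scores


def rank_probabilities(score_draws: dict[GeneticModel, np.ndarray]
                       ) -> tuple[list[GeneticModel], np.ndarray]:
    """Rank models per draw by their score, largest first.

    Returns the model order and a row-stochastic (model x rank) matrix;
    entry (m, r) is the probability model m attains rank r+1.
    """
    models = sorted(score_draws, key=lambda m: m.value)
    draws = np.stack([np.asarray(score_draws[m]) for m in models])  # (K, n)
    order = np.argsort(-draws, axis=0, kind="stable")
    ranks = np.argsort(order, axis=0)                              # (K, n)
    k, n = ranks.shape
    probs = np.stack([(ranks == r).mean(axis=1) for r in range(k)], axis=1)
    return models, probs


def sucra(rank_probs: np.ndarray) -> np.ndarray:
    """Surface under the cumulative ranking curve per model.

    sucra_k = sum_{r=1..K-1} CumP_k(r) / (K - 1) where CumP_k(r) is the
    probability model k is ranked within the top r.  1 = certainly best,
    0 = certainly worst; the mean over models is exactly 0.5.
    """
    probs = np.asarray(rank_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
        raise ValueError("rank matrix must be square (model x rank)")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rank matrix rows must each sum to 1")
    k = probs.shape[0]
    if k == 1:
        return np.array([1.0])
    cum = np.cumsum(probs, axis=1)[:, :k - 1]
    return cum.sum(axis=1) / (k - 1)


def rank_models(post: NmaPosterior, control_mix: Sequence[float],
                criterion: str = "z"):
    """Convenience: derive contrasts, rank and score in one call.

    Returns (models, rank_probability_matrix, sucra_scores).
    """
    contrasts = derive_model_contrasts(post, control_mix)
    scores = ranking_criterion(post, control_mix, contrasts, criterion)
    models, probs = rank_probabilities(scores)
    return models, probs, sucra(probs)
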