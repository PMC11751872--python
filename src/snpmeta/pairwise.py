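"""Pairwise meta-analysis: pooling, heterogeneity, sensitivity, bias.

Pooling is inverse-variance on the log-OR scale.  Heterogeneity is
quantified by Cochran's Q and I^2; the switching rule pools with a fixed
effect when the Q-test p exceeds 0.1 AND I^2 is below 50%, and with
DerSimonian-Laird random effects otherwise.  Leave-one-out, subgroup
analysis with a between-stratum Q test, method-of-moments mixed-effects
meta-regression, and Egger/Begg publication-bias tests (k >= 10) complete
the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .contrasts import EffectEstimate, GeneticModel
from .errors import InsufficientStudiesError

HET_P_THRESHOLD = 0.1   # Q-test p above this ...
HET_I2_THRESHOLD = 50.0  # ... and I^2 strictly below this -> fixed effect


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p_q: float
    i2: float       # percent, in [0, 100]
    tau2: float     # 0 under fixed-effect reporting


@dataclass(frozen=True)
class PooledResult:
    effect: EffectEstimate
    het: HeterogeneityResult
    method: str                      # "fixed" | "random"
    k: int
    model: Optional[GeneticModel] = None
    stratum: Optional[str] = None

    def relabel(self, model=None, stratum=None) -> "PooledResult":
        return replace(self, model=model if model is not None else self.model,
                       stratum=stratum if stratum is not None else self.stratum)


@dataclass(frozen=True)
class BiasTests:
    applicable: bool
    k: int
    egger_intercept: Optional[float] = None
    egger_p: Optional[float] = None
    begg_tau: Optional[float] = None
    begg_p: Optional[float] = None


def _arrays(effects: Sequence[EffectEstimate]):
    y = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    return y, se


def _heterogeneity(y: np.ndarray, se: np.ndarray) -> HeterogeneityResult:
    """Cochran Q at fixed-effect weights, with I^2 and DL tau^2."""
    w = 1.0 / se ** 2
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    df = len(y) - 1
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def _require_k(effects, k_min: int, what: str):
    if len(effects) < k_min:
        raise InsufficientStudiesError(
            f"{what} requires at least {k_min} studies, got {len(effects)}")


def pool_fixed(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling of log-ORs."""
    _require_k(effects, 2, "fixed-effect pooling")
    y, se = _arrays(effects)
    het = _heterogeneity(y, se)
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(math.sqrt(1.0 / np.sum(w)))
    het = replace(het, tau2=0.0)  # fixed-effect reporting convention
    return PooledResult(effect=EffectEstimate(pooled, pooled_se),
                        het=het, method="fixed", k=len(effects))


def pool_random(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 is the moment estimate from the fixed-effect Q; when Q <= df it
    truncates to zero and the estimate coincides with the fixed-effect
    one (only the reported method differs).
    """
    _require_k(effects, 2, "random-effects pooling")
    y, se = _arrays(effects)
    het = _heterogeneity(y, se)
    w_star = 1.0 / (se ** 2 + het.tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    pooled_se = float(math.sqrt(1.0 / np.sum(w_star)))
    return PooledResult(effect=EffectEstimate(pooled, pooled_se),
                        het=het, method="random", k=len(effects))


def uses_fixed_effect(het: HeterogeneityResult) -> bool:
    """The switching rule: fixed iff p_Q > 0.1 and I^2 < 50%."""
    return het.p_q > HET_P_THRESHOLD and het.i2 < HET_I2_THRESHOLD


def choose_and_pool(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Pool under the heterogeneity-driven fixed/random switching rule."""
    _require_k(effects, 2, "pooling")
    y, se = _arrays(effects)
    het = _heterogeneity(y, se)
    if uses_fixed_effect(het):
        return pool_fixed(effects)
    return pool_random(effects)


def leave_one_out(effects: Sequence[EffectEstimate]) -> list[PooledResult]:
    """Re-pool k times, omitting one study each time (k >= 3)."""
    _require_k(effects, 3, "leave-one-out")
    results = []
    for i in range(len(effects)):
        subset = [e for j, e in enumerate(effects) if j != i]
        results.append(choose_and_pool(subset).relabel(
            stratum=f"without:{effects[i].label or i}"))
    return results


@dataclass(frozen=True)
class SubgroupResult:
    strata: dict            # stratum label -> PooledResult
    descriptive_only: list  # strata with < 2 studies, not pooled
    q_between: Optional[float]
    df_between: Optional[int]
    p_between: Optional[float]


def subgroup_analysis(effects: Sequence[EffectEstimate],
                      labels: Sequence[str],
                      pooling: str = "random") -> SubgroupResult:
    """Per-stratum pooling plus a between-stratum heterogeneity Q test.

    pooling="random" pools every stratum with DL random effects (the
    convention for between-subgroup testing); pooling="rule" applies the
    fixed/random switching rule per stratum instead.  Strata with fewer
    than two studies are reported descriptively and excluded from the
    between-stratum test, which needs >= 2 poolable strata.
    """
    if len(effects) != len(labels):
        raise ValueError("labels must align with effects")
    groups: dict[str, list[EffectEstimate]] = {}
    for e, lab in zip(effects, labels):
        groups.setdefault(str(lab), []).append(e)
    strata, descriptive = {}, []
    for lab, group in sorted(groups.items()):
        if len(group) < 2:
            descriptive.append(lab)
            continue
        pooled = (pool_random(group) if pooling == "random"
                  else choose_and_pool(group))
        strata[lab] = pooled.relabel(stratum=lab)
    if len(strata) < 2:
        return SubgroupResult(strata=strata, descriptive_only=descriptive,
                              q_between=None, df_between=None, p_between=None)
    ys = np.array([r.effect.log_or for r in strata.values()])
    ws = np.array([1.0 / r.effect.se ** 2 for r in strata.values()])
    ybar = float(np.sum(ws * ys) / np.sum(ws))
    q_b = float(np.sum(ws * (ys - ybar) ** 2))
    df_b = len(strata) - 1
    p_b = float(stats.chi2.sf(q_b, df_b))
    return SubgroupResult(strata=strata, descriptive_only=descriptive,
                          q_between=q_b, df_between=df_b, p_between=p_b)


@dataclass(frozen=True)
class MetaRegressionResult:
    levels: list            # covariate levels; first is the reference
    coefficients: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tau2_residual: float


def meta_regression(effects: Sequence[EffectEstimate],
                    covariate: Sequence[str]) -> MetaRegressionResult:
    """Mixed-effects meta-regression with a categorical moderator.

    Dummy-codes the moderator (first level alphabetically is reference),
    estimates residual tau^2 by method of moments from the fixed-weight
    residual Q, then refits by weighted least squares with weights
    1 / (se^2 + tau^2).  Wald z-tests per coefficient.
    """
    _require_k(effects, 4, "meta-regression")
    labels = [str(c) for c in covariate]
    if len(labels) != len(effects):
        raise ValueError("covariate must align with effects")
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError("covariate must have at least two levels")
    y, se = _arrays(effects)
    k = len(y)
    x = np.ones((k, len(levels)))
    for j, lev in enumerate(levels[1:], start=1):
        x[:, j] = [1.0 if lab == lev else 0.0 for lab in labels]
    p = x.shape[1]
    if k <= p:
        raise InsufficientStudiesError(
            f"meta-regression needs k > {p} studies for {p} coefficients")

    w = 1.0 / se ** 2
    wx = x * w[:, None]
    xtwx = x.T @ wx
    beta_f = np.linalg.solve(xtwx, wx.T @ y)
    resid = y - x @ beta_f
    q_e = float(np.sum(w * resid ** 2))
    # method-of-moments residual tau^2: trace of the weighted projection
    h = np.linalg.solve(xtwx, wx.T)          # p x k
    trace_pw = float(np.sum(w) - np.trace(wx @ h))
    tau2 = max(0.0, (q_e - (k - p)) / trace_pw) if trace_pw > 0 else 0.0

    w_star = 1.0 / (se ** 2 + tau2)
    wx_s = x * w_star[:, None]
    cov = np.linalg.inv(x.T @ wx_s)
    beta = cov @ (wx_s.T @ y)
    beta_se = np.sqrt(np.diag(cov))
    z = beta / beta_se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return MetaRegressionResult(levels=levels, coefficients=beta,
                                se=beta_se, z=z, p=pvals,
                                tau2_residual=tau2)


def egger_test(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Egger regression asymmetry test.

    OLS of the standardized effect y/se on precision 1/se; returns the
    intercept and its two-sided t-test p-value (k - 2 df).
    """
    _require_k(effects, 3, "Egger's test")
    y, se = _arrays(effects)
    snd = y / se
    prec = 1.0 / se
    res = stats.linregress(prec, snd)
    df = len(y) - 2
    if res.intercept_stderr == 0.0:  # perfectly collinear funnel
        return float(res.intercept), 1.0 if res.intercept == 0.0 else 0.0
    t = res.intercept / res.intercept_stderr
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(res.intercept), p


def begg_test(effects: Sequence[EffectEstimate]) -> tuple[float, float]:
    """Begg-Mazumdar rank correlation test.

    Kendall tau-b between the standardized deviates from the fixed-effect
    pooled estimate, v_i = (y_i - ybar) / sqrt(se_i^2 - 1/sum(w)), and the
    per-study variances; normal-approximation p-value.
    """
    _require_k(effects, 3, "Begg's test")
    y, se = _arrays(effects)
    w = 1.0 / se ** 2
    ybar = float(np.sum(w * y) / np.sum(w))
    pooled_var = 1.0 / float(np.sum(w))
    denom = np.sqrt(np.maximum(se ** 2 - pooled_var, 1e-12))
    deviates = (y - ybar) / denom
    tau, p = stats.kendalltau(deviates, se ** 2)
    return float(tau), float(p)


def bias_tests(effects: Sequence[EffectEstimate],
               k_min: int = 10) -> BiasTests:
    """Run Begg and Egger tests when k >= k_min, else mark inapplicable."""
    k = len(effects)
    if k < k_min:
        return BiasTests(applicable=False, k=k)
    intercept, egger_p = egger_test(effects)
    tau, begg_p = begg_test(effects)
    return BiasTests(applicable=True, k=k, egger_intercept=intercept,
                     egger_p=egger_p, begg_tau=tau, begg_p=begg_p)
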