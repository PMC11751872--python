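"""Diagnostic-accuracy meta-analysis of a risk-genotype dichotomization.

Treating carriage of the risk grouping as a positive "test" for disease,
each study yields a TP/FP/FN/TN table (the same 2x2 as the pairwise
contrast, so the diagnostic odds ratio equals that contrast's OR
exactly).  Sensitivity and specificity are pooled on the logit scale and
the DOR on the log scale, under the same fixed/random switching rule as
the pairwise module.  The Moses-Littenberg SROC regression
D = a + b S (D = logit TPR - logit FPR, S = their sum) summarizes the
curve, with AUC by numerical integration; the Spearman correlation
between logit TPR and logit FPR screens for a threshold effect.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .contrasts import EffectEstimate, TwoByTwo, Z95
from .errors import DegenerateTableError, InsufficientStudiesError
from .pairwise import PooledResult, choose_and_pool


@dataclass(frozen=True)
class DiagnosticStudy:
    """TP/FP/FN/TN counts: tp = cases carrying the risk grouping,
    fp = controls carrying it."""

    tp: float
    fp: float
    fn: float
    tn: float
    continuity_added: bool = False

    @classmethod
    def from_two_by_two(cls, table: TwoByTwo) -> "DiagnosticStudy":
        return cls(tp=table.a, fp=table.c, fn=table.b, tn=table.d,
                   continuity_added=table.continuity_added)

    def corrected(self) -> "DiagnosticStudy":
        if min(self.tp, self.fp, self.fn, self.tn) > 0:
            return self
        return DiagnosticStudy(self.tp + 0.5, self.fp + 0.5,
                               self.fn + 0.5, self.tn + 0.5,
                               continuity_added=True)

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)


@dataclass(frozen=True)
class RatioCI:
    value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class AccuracyStats:
    sens: RatioCI
    spec: RatioCI
    plr: RatioCI
    nlr: RatioCI
    dor: RatioCI
    continuity_added: bool


def _proportion_ci(x: float, n: float) -> RatioCI:
    """Logit-scale Wald interval for a proportion."""
    p = x / n
    if x == 0 or x == n:   # corrected cells keep us off the boundary
        return RatioCI(p, 0.0, 1.0)
    lo = float(expit(logit(p) - Z95 * math.sqrt(1 / x + 1 / (n - x))))
    hi = float(expit(logit(p) + Z95 * math.sqrt(1 / x + 1 / (n - x))))
    return RatioCI(p, lo, hi)


def _ratio_ci(value: float, log_se: float) -> RatioCI:
    return RatioCI(value, value * math.exp(-Z95 * log_se),
                   value * math.exp(Z95 * log_se))


def accuracy_stats(study: DiagnosticStudy) -> AccuracyStats:
    """Per-study sensitivity, specificity, likelihood ratios and DOR.

    A zero cell triggers the 0.5 correction on all four cells.  DOR =
    (tp*tn)/(fp*fn) = PLR/NLR is algebraically the odds ratio of the
    underlying 2x2.
    """
    s = study.corrected()
    if min(s.tp + s.fn, s.fp + s.tn) <= 0:
        raise DegenerateTableError("empty case or control margin")
    sens = _proportion_ci(s.tp, s.tp + s.fn)
    spec = _proportion_ci(s.tn, s.fp + s.tn)
    plr_val = sens.value / (1.0 - spec.value)
    nlr_val = (1.0 - sens.value) / spec.value
    dor_val = (s.tp * s.tn) / (s.fp * s.fn)
    # delta-method log-scale SEs
    se_plr = math.sqrt((1 - sens.value) / s.tp + spec.value / s.fp)
    se_nlr = math.sqrt(sens.value / s.fn + (1 - spec.value) / s.tn)
    se_dor = math.sqrt(1 / s.tp + 1 / s.fp + 1 / s.fn + 1 / s.tn)
    return AccuracyStats(
        sens=sens, spec=spec,
        plr=_ratio_ci(plr_val, se_plr),
        nlr=_ratio_ci(nlr_val, se_nlr),
        dor=_ratio_ci(dor_val, se_dor),
        continuity_added=s.continuity_added,
    )


@dataclass(frozen=True)
class PooledAccuracy:
    sens: RatioCI
    spec: RatioCI
    plr: RatioCI
    nlr: RatioCI
    dor: RatioCI
    dor_pooled: PooledResult    # full pooled result on the log-DOR scale
    method: str


def _pool_logit(xs, ns) -> tuple[PooledResult, RatioCI]:
    effects = []
    for x, n in zip(xs, ns):
        se = math.sqrt(1.0 / x + 1.0 / (n - x))
        effects.append(EffectEstimate(float(logit(x / n)), se))
    pooled = choose_and_pool(effects)
    e = pooled.effect
    return pooled, RatioCI(float(expit(e.log_or)),
                           float(expit(e.log_or - Z95 * e.se)),
                           float(expit(e.log_or + Z95 * e.se)))


def pool_accuracy(studies: Sequence[DiagnosticStudy]) -> PooledAccuracy:
    """Pool accuracy measures across studies (k >= 2).

    Sensitivity and specificity are pooled on the logit scale and the
    DOR on the log scale, each by inverse variance under the fixed/random
    switching rule.  Likelihood ratios are derived from the pooled
    sensitivity and specificity.
    """
    if len(studies) < 2:
        raise InsufficientStudiesError("pooling requires k >= 2 studies")
    ss = [s.corrected() for s in studies]
    _, sens = _pool_logit([s.tp for s in ss],
                          [s.tp + s.fn for s in ss])
    _, spec = _pool_logit([s.tn for s in ss],
                          [s.fp + s.tn for s in ss])
    dor_effects = [
        EffectEstimate(
            math.log(s.tp * s.tn / (s.fp * s.fn)),
            math.sqrt(1 / s.tp + 1 / s.fp + 1 / s.fn + 1 / s.tn))
        for s in ss]
    dor_pooled = choose_and_pool(dor_effects)
    e = dor_pooled.effect
    dor = RatioCI(e.odds_ratio, e.ci_low, e.ci_high)
    plr_val = sens.value / (1.0 - spec.value)
    nlr_val = (1.0 - sens.value) / spec.value
    # conservative CI for derived LRs: combine logit-scale variances
    return PooledAccuracy(
        sens=sens, spec=spec,
        plr=RatioCI(plr_val, float("nan"), float("nan")),
        nlr=RatioCI(nlr_val, float("nan"), float("nan")),
        dor=dor, dor_pooled=dor_pooled, method=dor_pooled.method)


@dataclass(frozen=True)
class SrocModel:
    a_intercept: float
    b_slope: float
    auc: float
    se_auc: Optional[float]
    symmetric_forced: bool = False

    def tpr_at(self, fpr: np.ndarray) -> np.ndarray:
        """Implied SROC curve TPR(FPR) from the Moses fit."""
        v = logit(fpr)
        u = (self.a_intercept + (1.0 + self.b_slope) * v) / (1.0 - self.b_slope)
        return expit(u)


def _moses_fit(d: np.ndarray, s: np.ndarray) -> tuple[float, float, bool]:
    if np.var(s) <= 1e-12:
        return float(np.mean(d)), 0.0, True
    b, a = np.polyfit(s, d, 1)
    return float(a), float(b), False


def _auc_from_fit(a: float, b: float, n_points: int = 2000) -> float:
    """Midpoint quadrature of the implied curve over FPR in (0, 1)."""
    fpr = (np.arange(n_points) + 0.5) / n_points
    v = logit(fpr)
    u = (a + (1.0 + b) * v) / (1.0 - b)
    return float(np.mean(expit(u)))


def sroc_moses(studies: Sequence[DiagnosticStudy],
               n_points: int = 2000,
               n_boot: int = 0,
               seed: int = 0) -> SrocModel:
    """Moses-Littenberg SROC regression with numerically integrated AUC.

    Unweighted least squares of D on S over the k >= 3 studies; the AUC
    integrates the implied TPR(FPR) curve over the full unit interval by
    midpoint quadrature (``n_points`` >= 1000 recommended).  With
    ``n_boot`` > 0 the AUC standard error is estimated by a seeded
    bootstrap over studies; otherwise se_auc is None.  Degenerate S
    variance (all studies at one threshold) forces a symmetric curve
    (b = 0).
    """
    if len(studies) < 3:
        raise InsufficientStudiesError("SROC fit requires k >= 3 studies")
    ss = [s.corrected() for s in studies]
    tpr = np.array([s.tpr for s in ss])
    fpr = np.array([s.fpr for s in ss])
    if np.any((tpr <= 0) | (tpr >= 1) | (fpr <= 0) | (fpr >= 1)):
        raise DegenerateTableError("TPR/FPR must be inside (0,1) after "
                                   "continuity correction")
    d = logit(tpr) - logit(fpr)
    s_ = logit(tpr) + logit(fpr)
    a, b, forced = _moses_fit(d, s_)
    if abs(1.0 - b) < 1e-8:
        raise DegenerateTableError("Moses slope of 1 leaves the SROC "
                                   "curve undefined")
    auc = _auc_from_fit(a, b, n_points)
    se_auc = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        k = len(ss)
        aucs = []
        for _ in range(n_boot):
            idx = rng.integers(0, k, size=k)
            if np.var(s_[idx]) <= 1e-12 and np.var(d[idx]) <= 1e-12:
                continue
            ab, bb, _f = _moses_fit(d[idx], s_[idx])
            if abs(1.0 - bb) < 1e-8:
                continue
            aucs.append(_auc_from_fit(ab, bb, max(200, n_points // 4)))
        if len(aucs) > 1:
            se_auc = float(np.std(aucs, ddof=1))
    return SrocModel(a_intercept=a, b_slope=b, auc=auc, se_auc=se_auc,
                     symmetric_forced=forced)


def spearman_threshold(studies: Sequence[DiagnosticStudy]
                       ) -> tuple[float, float]:
    """Spearman correlation between logit TPR and logit FPR.

    A strong positive correlation indicates heterogeneity driven by a
    threshold effect.  Exact permutation p-value for k <= 9 (conditional
    on the observed rank patterns, average ranks on ties); t
    approximation for larger k.
    """
    if len(studies) < 3:
        raise InsufficientStudiesError("threshold test requires k >= 3")
    ss = [s.corrected() for s in studies]
    x = logit(np.array([s.tpr for s in ss]))
    y = logit(np.array([s.fpr for s in ss]))
    rho = float(stats.spearmanr(x, y).statistic)
    k = len(ss)
    if k <= 9:
        rx = stats.rankdata(x) - (k + 1) / 2.0
        ry = stats.rankdata(y) - (k + 1) / 2.0
        # |rho| is monotone in |rx . ry_perm|, so count on the dot product
        observed = abs(float(rx @ ry))
        perms = np.array(list(itertools.permutations(range(k))))
        dots = np.abs(ry[perms] @ rx)
        p = float(np.mean(dots >= observed - 1e-9))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, float(p)
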