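"""Genetic-model selection: Thakkinstian's algorithm, FPRP, decisions.

Thakkinstian's algorithm compares three pooled pairwise odds ratios --
OR1 (22 vs 11), OR2 (12 vs 11) and OR3 (22 vs 12) -- and proposes an
inheritance model from their significance pattern:

    OR1 = OR3 != 1 and OR2 = 1              -> recessive
    OR1 = OR2 != 1 and OR3 = 1              -> dominant
    OR2 = 1/OR3 != 1 and OR1 = 1            -> complete over-dominant
    OR1 > OR2 > 1 and OR1 > OR3 > 1
      (or the all-below-1 mirror)           -> codominant

"= 1" is judged by the 95% CI containing 1 and "!= 1" by it excluding 1;
the reciprocal condition OR2 = 1/OR3 is a z-test of log(OR2) + log(OR3);
inequality chains use point estimates under those significance
conditions.  Rules are evaluated in the order above; no match means
undetermined.

The false positive report probability (Wacholder) for an observed effect
is FPRP = alpha(1-pi) / [alpha(1-pi) + (1-beta) pi], with alpha the
observed two-sided p-value, 1-beta the power to detect a threshold OR
(default 1.5) at a critical value equal to the observed z, and pi the
prior probability of a true association.  An association is noteworthy
when FPRP < 0.2 at pi = 0.01.

The composite decision: candidate models are those significant in the
pairwise meta-analysis AND proposed by the network meta-analysis or
Thakkinstian's algorithm (or both), with at least two contributing
studies; definitive models are candidates whose FPRP is noteworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.stats import norm

from .contrasts import EffectEstimate, GeneticModel

DEFAULT_PRIORS = (0.1, 0.01, 0.001, 0.0001, 0.00001)
NOTEWORTHY_PRIOR = 0.01
NOTEWORTHY_CUTOFF = 0.2
DEFAULT_THRESHOLD_OR = 1.5


@dataclass(frozen=True)
class ThakkinstianInput:
    """The three pooled contrasts the algorithm compares.

    or1: variant homozygote vs common homozygote (22 vs 11)
    or2: heterozygote vs common homozygote (12 vs 11)
    or3: variant homozygote vs heterozygote (22 vs 12)
    All three must be pooled from the same study set.
    """

    or1: EffectEstimate
    or2: EffectEstimate
    or3: EffectEstimate


@dataclass(frozen=True)
class ModelVerdict:
    proposed: str    # recessive | dominant | complete_overdominant |
                     # codominant | undetermined
    rule_fired: str


#: Verdicts mapped onto the six pairwise genetic models for the candidate
#: intersection.  "codominant" (effect ordered by variant-allele count)
#: has no single counterpart among the six; the allele-dose contrasts
#: (allelic, homozygote) are its nearest representatives.
VERDICT_TO_MODELS = {
    "recessive": {GeneticModel.RECESSIVE},
    "dominant": {GeneticModel.DOMINANT},
    "complete_overdominant": {GeneticModel.OVERDOMINANT},
    "codominant": {GeneticModel.ALLELIC, GeneticModel.HOMOZYGOTE},
    "undetermined": set(),
}


def _sig(e: EffectEstimate, alpha: float) -> bool:
    """CI excludes OR = 1 at the given level."""
    return e.p_value < alpha


def thakkinstian_decide(inp: ThakkinstianInput,
                        alpha: float = 0.05) -> ModelVerdict:
    """Propose an inheritance model from the OR1/OR2/OR3 pattern."""
    or1, or2, or3 = inp.or1, inp.or2, inp.or3
    s1, s2, s3 = (_sig(e, alpha) for e in (or1, or2, or3))

    if s1 and s3 and not s2:
        return ModelVerdict("recessive", "OR1 = OR3 != 1 and OR2 = 1")
    if s1 and s2 and not s3:
        return ModelVerdict("dominant", "OR1 = OR2 != 1 and OR3 = 1")
    if s2 and s3 and not s1:
        # reciprocal check: log(OR2) + log(OR3) compatible with 0
        z = abs(or2.log_or + or3.log_or) / math.sqrt(
            or2.se ** 2 + or3.se ** 2)
        if 2.0 * float(norm.sf(z)) >= alpha:
            return ModelVerdict("complete_overdominant",
                                "OR2 = 1/OR3 != 1 and OR1 = 1")
    if s1 and s2 and s3:
        v1, v2, v3 = or1.odds_ratio, or2.odds_ratio, or3.odds_ratio
        if (v1 > v2 > 1 and v1 > v3 > 1) or (v1 < v2 < 1 and v1 < v3 < 1):
            return ModelVerdict(
                "codominant",
                "OR1 > OR2 > 1 and OR1 > OR3 > 1 (or mirrored below 1)")
    return ModelVerdict("undetermined", "no rule matched")


@dataclass(frozen=True)
class FprpResult:
    alpha_obs: float
    power: float
    fprp_by_prior: dict        # prior -> FPRP
    noteworthy: bool
    threshold_or: float

    def at(self, prior: float) -> float:
        return self.fprp_by_prior[prior]


def fprp(effect: EffectEstimate,
         threshold_or: float = DEFAULT_THRESHOLD_OR,
         priors: Sequence[float] = DEFAULT_PRIORS,
         alpha_mode: str = "observed",
         fixed_alpha: float = 0.05) -> FprpResult:
    """False positive report probability for an observed pooled effect.

    With z_obs = |log OR| / se and delta = |ln threshold_or|:

        alpha = 2 Phi(-z_obs)                       (observed p)
        power = Phi(delta/se - z*) + Phi(-delta/se - z*)
        FPRP(pi) = alpha (1-pi) / [alpha (1-pi) + power * pi]

    where the critical value z* equals z_obs under the default
    ``alpha_mode="observed"`` (the spreadsheet convention that the alpha
    level is set to the observed p-value) or the fixed-level quantile
    under ``alpha_mode="fixed"``.  Protective effects are handled by the
    absolute values: an OR below 1 is tested against 1/threshold_or,
    which is identical under |ln OR|.

    The result is noteworthy when FPRP < 0.2 at prior 0.01 (the prior is
    added to the evaluated set if absent).
    """
    if threshold_or <= 0:
        raise ValueError("threshold OR must be positive")
    z_obs = abs(effect.log_or) / effect.se
    alpha = 2.0 * float(norm.sf(z_obs))  # z_obs = 0 -> alpha = 1
    if alpha_mode == "observed":
        z_crit = z_obs
    elif alpha_mode == "fixed":
        z_crit = float(norm.ppf(1.0 - fixed_alpha / 2.0))
    else:
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    delta = abs(math.log(threshold_or)) / effect.se
    power = float(norm.cdf(delta - z_crit) + norm.cdf(-delta - z_crit))

    eval_priors = list(priors)
    if NOTEWORTHY_PRIOR not in eval_priors:
        eval_priors.append(NOTEWORTHY_PRIOR)
    by_prior = {}
    for pi in eval_priors:
        if not 0.0 < pi <= 1.0:
            raise ValueError(f"prior must be in (0, 1], got {pi}")
        num = alpha * (1.0 - pi)
        den = num + power * pi
        by_prior[pi] = num / den if den > 0 else 1.0
    noteworthy = by_prior[NOTEWORTHY_PRIOR] < NOTEWORTHY_CUTOFF
    return FprpResult(alpha_obs=alpha, power=power, fprp_by_prior=by_prior,
                      noteworthy=noteworthy, threshold_or=threshold_or)


@dataclass
class ModelDecision:
    """Per-(SNP, stratum) record mirroring the decision-table columns."""

    snp_id: str
    stratum: str
    k: int
    significant_models: set
    nma_best: Optional[GeneticModel]
    thakkinstian: ModelVerdict
    candidates: set
    fprp_at_001: dict             # candidate model -> FPRP at prior 0.01
    definitive: set
    direction: str                # hazardous | protective | none
    incomplete: bool = False
    notes: list = field(default_factory=list)

    def to_row(self) -> dict:
        fmt = lambda ms: ", ".join(sorted(m.value for m in ms)) or "/"
        return {
            "snp_id": self.snp_id, "stratum": self.stratum, "k": self.k,
            "significant_models": fmt(self.significant_models),
            "nma_best": self.nma_best.value if self.nma_best else "NA",
            "thakkinstian": self.thakkinstian.proposed,
            "candidates": fmt(self.candidates),
            "fprp_at_0.01": "; ".join(
                f"{m.value}={v:.3g}"
                for m, v in sorted(self.fprp_at_001.items(),
                                   key=lambda kv: kv[0].value)) or "/",
            "definitive": fmt(self.definitive),
            "direction": self.direction,
        }


def decide(snp_id: str,
           stratum: str,
           k: int,
           significant: dict,
           thakkinstian: ModelVerdict,
           fprp_results: dict,
           nma_best: Optional[GeneticModel] = None,
           pooled_or: Optional[dict] = None) -> ModelDecision:
    """Combine the pipeline stages into the candidate/definitive verdict.

    Parameters
    ----------
    significant : {GeneticModel: pooled EffectEstimate} for the models
        whose pairwise pooled CI excludes 1.
    thakkinstian : the algorithm's verdict for this (SNP, stratum).
    fprp_results : {GeneticModel: FprpResult} for at least every
        candidate model; missing candidates mark the decision incomplete.
    nma_best : highest-SUCRA model, or None when the MCMC stage was not
        run (Thakkinstian's proposal alone then defines the proposal set).
    pooled_or : optional {GeneticModel: odds ratio} used to call the risk
        direction of the definitive models.
    """
    sig_models = set(significant)
    proposed = set(VERDICT_TO_MODELS[thakkinstian.proposed])
    if nma_best is not None:
        proposed = proposed | {GeneticModel(nma_best)}
    candidates = sig_models & proposed if k >= 2 else set()

    notes = []
    if k < 2 and sig_models & proposed:
        notes.append("fewer than 2 studies: candidates suppressed")

    definitive = set()
    fprp_at = {}
    incomplete = False
    for m in candidates:
        res = fprp_results.get(m)
        if res is None:
            incomplete = True
            notes.append(f"missing FPRP for candidate {m.value}")
            continue
        fprp_at[m] = res.at(NOTEWORTHY_PRIOR)
        if res.noteworthy:
            definitive.add(m)

    direction = "none"
    if definitive:
        ors = []
        for m in definitive:
            if pooled_or and m in pooled_or:
                ors.append(pooled_or[m])
            elif m in significant:
                ors.append(significant[m].odds_ratio)
        if ors:
            direction = "hazardous" if all(v > 1 for v in ors) else (
                "protective" if all(v < 1 for v in ors) else "mixed")

    return ModelDecision(
        snp_id=snp_id, stratum=stratum, k=k,
        significant_models=sig_models, nma_best=nma_best,
        thakkinstian=thakkinstian, candidates=candidates,
        fprp_at_001=fprp_at, definitive=definitive,
        direction=direction, incomplete=incomplete, notes=notes)


def pick_nma_best(models: Sequence[GeneticModel], sucra_scores,
                  thakkinstian: Optional[ModelVerdict] = None
                  ) -> GeneticModel:
    """Highest-SUCRA model; ties break toward the Thakkinstian proposal,
    then lexicographically."""
    best = max(sucra_scores)
    tied = [m for m, s in zip(models, sucra_scores) if s == best]
    if len(tied) > 1 and thakkinstian is not None:
        preferred = VERDICT_TO_MODELS[thakkinstian.proposed]
        pref_tied = [m for m in tied if m in preferred]
        if pref_tied:
            tied = pref_tied
    return sorted(tied, key=lambda m: m.value)[0]
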