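"""Genetic-model contrasts and per-study odds ratios.

A biallelic SNP has three genotypes: common homozygote (11), heterozygote
(12) and variant homozygote (22), with allele "2" the declared variant
allele.  Each of the six classical genetic models dichotomizes the three
genotypes into an exposed / unexposed grouping, yielding a 2x2 table per
case-control study from which an odds ratio is estimated on the log scale
(Woolf standard error, Haldane-Anscombe 0.5 correction on zero cells).

The variant-bearing grouping is always "exposed", so ORs below 1 read as
protective.  The reference for the homozygote and heterozygote models is
the common homozygote.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from scipy.stats import norm

from .errors import DegenerateTableError

# two-sided 95% normal quantile, used for every CI in the package
Z95: float = float(norm.ppf(0.975))


class GeneticModel(str, enum.Enum):
    """The six genotype dichotomizations.

    allelic       variant allele vs common allele (allele counts, 2n each)
    homozygote    22 vs 11 (heterozygotes excluded)
    heterozygote  12 vs 11 (variant homozygotes excluded)
    dominant      12+22 vs 11 (variant carriers vs non-carriers)
    recessive     22 vs 11+12
    overdominant  12 vs 11+22
    """

    ALLELIC = "allelic"
    HOMOZYGOTE = "homozygote"
    HETEROZYGOTE = "heterozygote"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    OVERDOMINANT = "overdominant"


#: (exposed, unexposed) cell builders, as functions of a genotype triple.
_GROUPINGS = {
    GeneticModel.ALLELIC: lambda n: (2 * n[2] + n[1], 2 * n[0] + n[1]),
    GeneticModel.HOMOZYGOTE: lambda n: (n[2], n[0]),
    GeneticModel.HETEROZYGOTE: lambda n: (n[1], n[0]),
    GeneticModel.DOMINANT: lambda n: (n[1] + n[2], n[0]),
    GeneticModel.RECESSIVE: lambda n: (n[2], n[0] + n[1]),
    GeneticModel.OVERDOMINANT: lambda n: (n[1], n[0] + n[2]),
}


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-status 2x2 table.

    a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.  Cells are floats so the 0.5 continuity
    correction can be represented; raw tables have integer values.
    """

    a: float
    b: float
    c: float
    d: float
    continuity_added: bool = False

    def corrected(self) -> "TwoByTwo":
        """Return the table with 0.5 added to every cell if any cell is 0."""
        if min(self.a, self.b, self.c, self.d) > 0:
            return self
        return TwoByTwo(self.a + 0.5, self.b + 0.5, self.c + 0.5,
                        self.d + 0.5, continuity_added=True)


@dataclass(frozen=True)
class EffectEstimate:
    """A log odds ratio with its standard error.

    CI bounds and the two-sided p-value are derived on demand:
    ci = exp(log_or -+ z_{.975} * se), p = 2 * Phi(-|log_or| / se).
    The same type carries per-study and pooled effects.
    """

    log_or: float
    se: float
    label: str = field(default="", compare=False)

    def __post_init__(self):
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"standard error must be positive, got {self.se}")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z95 * self.se)

    @property
    def p_value(self) -> float:
        return 2.0 * float(norm.sf(abs(self.log_or) / self.se))

    @property
    def significant(self) -> bool:
        """True when the 95% CI excludes OR = 1."""
        return self.p_value < 0.05

    @classmethod
    def from_or_ci(cls, odds_ratio: float, ci_low: float, ci_high: float,
                   label: str = "") -> "EffectEstimate":
        """Reconstruct log-OR and SE from a printed OR with 95% CI.

        se = (ln hi - ln lo) / (2 * z_{.975}); the point estimate is taken
        from the printed OR, not the CI midpoint.
        """
        if not (0 < ci_low <= odds_ratio <= ci_high):
            raise ValueError(
                f"inconsistent OR/CI: {odds_ratio} not in [{ci_low}, {ci_high}]")
        se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
        return cls(log_or=math.log(odds_ratio), se=se, label=label)


def build_contrast(case_counts, control_counts,
                   model: GeneticModel) -> TwoByTwo:
    """Collapse genotype triples into the model's exposed/unexposed 2x2.

    Parameters
    ----------
    case_counts, control_counts : (n11, n12, n22) genotype count triples.
    model : which dichotomization to apply.

    For the allelic model the cells are allele counts (2*hom + het), so
    the table margins are twice the subject counts.
    """
    grouping = _GROUPINGS[GeneticModel(model)]
    a, b = grouping(tuple(case_counts))
    c, d = grouping(tuple(control_counts))
    return TwoByTwo(float(a), float(b), float(c), float(d))


def estimate_or(table: TwoByTwo, label: str = "") -> EffectEstimate:
    """Woolf log odds ratio with its standard error from a 2x2 table.

    Zero cells trigger the Haldane-Anscombe correction (0.5 added to all
    four cells).  A margin that is empty even after correction -- both
    cells of the exposed or unexposed column, or of the case or control
    row, equal to zero in the raw table -- leaves the OR undefined.
    """
    raw = (table.a, table.b, table.c, table.d)
    if (table.a == 0 and table.c == 0) or (table.b == 0 and table.d == 0) \
            or (table.a == 0 and table.b == 0) or (table.c == 0 and table.d == 0):
        raise DegenerateTableError(
            f"odds ratio undefined: empty margin in table a,b,c,d = {raw}")
    t = table.corrected()
    log_or = math.log(t.a * t.d / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return EffectEstimate(log_or=log_or, se=se, label=label)


def study_effect(study, model: GeneticModel) -> EffectEstimate:
    """Per-study effect for one genetic model (convenience wrapper)."""
    table = build_contrast(study.case_counts, study.control_counts, model)
    return estimate_or(table, label=study.study_id)


def build_or3_contrast(case_counts, control_counts) -> TwoByTwo:
    """22 vs 12 table (OR3 of Thakkinstian's algorithm).

    Not one of the six reported genetic models, but required by the
    model-selection rules: exposed = variant homozygote, unexposed =
    heterozygote, common homozygotes excluded.
    """
    a, b = case_counts[2], case_counts[1]
    c, d = control_counts[2], control_counts[1]
    return TwoByTwo(float(a), float(b), float(c), float(d))
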