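"""Synthetic case-control genotype corpora with known truth.

Controls are drawn from exact Hardy-Weinberg proportions at a chosen
variant-allele frequency.  Case genotype distributions are obtained by
tilting the control distribution with per-genotype odds multipliers
determined by the generative genetic model and a study-specific odds
ratio (drawn around the true OR with log-normal between-study
heterogeneity).  Because the tilting is an exact odds-multiplier
construction, the population odds ratio of the generating contrast
equals the study OR by construction, which makes parameter-recovery
tests sharp.

Default corpus shape mirrors a typical SNP-association literature: ~10
studies per SNP, study totals of a few hundred to a couple of thousand
subjects, mostly Asian with a Caucasian minority, modest heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np

from .contrasts import GeneticModel
from .studies import GenotypeStudy

SizeSpec = Union[int, tuple[int, int]]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the standard study conditions."""

    snp_id: str = "rs0000001"
    k_studies: int = 10
    n_cases: SizeSpec = (150, 1200)
    n_controls: SizeSpec = (150, 1200)
    maf: float = 0.3
    true_model: GeneticModel = GeneticModel.RECESSIVE
    true_or: float = 1.5
    tau: float = 0.1
    ethnicity_split: tuple = (("Asian", 0.72), ("Caucasian", 0.28))
    het_exponent: float = 0.5   # codominant heterozygote exponent
    gene: str = "GENE1"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must be inside (0, 1)")
        if self.k_studies < 1:
            raise ValueError("k_studies must be >= 1")
        if self.true_or <= 0 or self.tau < 0:
            raise ValueError("true_or must be > 0 and tau >= 0")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated corpus."""

    snp_id: str
    true_model: str
    true_or: float
    tau: float
    maf: float
    control_probs: tuple
    study_log_or: list = field(default_factory=list)
    study_ethnicity: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def genotype_probs_hwe(maf: float) -> tuple[float, float, float]:
    """Exact HWE genotype probabilities ((1-q)^2, 2q(1-q), q^2)."""
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be strictly inside (0, 1)")
    q = maf
    return ((1 - q) ** 2, 2 * q * (1 - q), q ** 2)


def _multipliers(model: GeneticModel, psi: float, het_exponent: float):
    model = GeneticModel(model)
    if model is GeneticModel.RECESSIVE:
        return (1.0, 1.0, psi)
    if model is GeneticModel.DOMINANT:
        return (1.0, psi, psi)
    if model is GeneticModel.OVERDOMINANT:
        return (1.0, psi, 1.0)
    if model is GeneticModel.ALLELIC:
        return (1.0, psi, psi ** 2)
    if model in (GeneticModel.HOMOZYGOTE, GeneticModel.HETEROZYGOTE):
        # codominant-style dose response: psi^h for hets, psi for homs
        if model is GeneticModel.HETEROZYGOTE:
            return (1.0, psi, psi ** het_exponent)
        return (1.0, psi ** het_exponent, psi)
    raise ValueError(f"unknown genetic model {model!r}")


def case_probs(control_probs: Sequence[float], model: GeneticModel,
               or_study: float, het_exponent: float = 0.5
               ) -> tuple[float, float, float]:
    """Case genotype distribution implied by a generative model and OR.

    Each genotype's control probability is multiplied by its exposure
    odds multiplier (recessive: (1, 1, psi); dominant: (1, psi, psi);
    over-dominant: (1, psi, 1); allelic: (1, psi, psi^2); homozygote /
    codominant: (1, psi^h, psi)) and renormalized; for case-control
    sampling this makes the generating contrast's OR exactly psi.
    """
    if or_study <= 0:
        raise ValueError("or_study must be positive")
    p = np.asarray(control_probs, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("control_probs must be a probability triple")
    m = np.array(_multipliers(model, or_study, het_exponent))
    q = p * m
    q = q / q.sum()
    return tuple(float(v) for v in q)


def _draw_size(rng: np.random.Generator, spec: SizeSpec) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def simulate_corpus(config: SimConfig
                    ) -> tuple[list[GenotypeStudy], SimTruth]:
    """Draw a fully reproducible corpus of case-control genotype studies.

    Per study: a study log-OR ~ Normal(ln true_or, tau^2); control
    genotypes ~ Multinomial(n_controls, HWE probs at ``maf``); case
    genotypes ~ Multinomial(n_cases, tilted probs at the study OR).
    Ethnicity labels are drawn from ``ethnicity_split``; genotyping
    method alternates between the two common platforms to exercise
    method-based subgroups.
    """
    rng = np.random.default_rng(config.seed)
    p_ctrl = genotype_probs_hwe(config.maf)
    labels = [lab for lab, _w in config.ethnicity_split]
    weights = np.array([w for _lab, w in config.ethnicity_split], dtype=float)
    weights = weights / weights.sum()

    truth = SimTruth(snp_id=config.snp_id,
                     true_model=GeneticModel(config.true_model).value,
                     true_or=config.true_or, tau=config.tau,
                     maf=config.maf, control_probs=p_ctrl)
    studies = []
    methods = ("RFLP-PCR", "TaqMan")
    for i in range(config.k_studies):
        log_or_i = rng.normal(np.log(config.true_or), config.tau)
        n_cases = _draw_size(rng, config.n_cases)
        n_controls = _draw_size(rng, config.n_controls)
        q_case = case_probs(p_ctrl, config.true_model,
                            float(np.exp(log_or_i)), config.het_exponent)
        case_counts = tuple(int(c) for c in
                            rng.multinomial(n_cases, q_case))
        control_counts = tuple(int(c) for c in
                               rng.multinomial(n_controls, p_ctrl))
        ethnicity = str(rng.choice(labels, p=weights))
        studies.append(GenotypeStudy(
            study_id=f"sim{i + 1:03d}",
            snp_id=config.snp_id,
            gene=config.gene,
            ethnicity=ethnicity,
            control_source="population",
            genotyping_method=methods[i % 2],
            case_counts=case_counts,
            control_counts=control_counts,
            quality_total=int(rng.integers(8, 15)),
        ))
        truth.study_log_or.append(float(log_or_i))
        truth.study_ethnicity.append(ethnicity)
    return studies, truth
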