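import pytest

from snpmeta import GenotypeStudy, SimConfig, GeneticModel, simulate_corpus


@pytest.fixture
def study():
    """A single well-behaved study with HWE controls at q = 0.4."""
    return GenotypeStudy(
        study_id="s1", snp_id="rs1", gene="G1", ethnicity="Asian",
        control_source="population", genotyping_method="TaqMan",
        case_counts=(10, 20, 30), control_counts=(36, 48, 16),
        quality_total=12,
    )


@pytest.fixture
def recessive_corpus():
    """Ten simulated studies with a known recessive effect (OR 1.6)."""
    config = SimConfig(k_studies=10, n_cases=1000, n_controls=1000,
                       maf=0.3, true_model=GeneticModel.RECESSIVE,
                       true_or=1.6, tau=0.05, seed=42)
    studies, truth = simulate_corpus(config)
    return studies, truth
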