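# Methods

This note documents the statistical models behind `snpmeta`, the choices
made where the methodology is genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Effect estimation and pooling

Per-study effects are Woolf log odds ratios: for a 2×2 table (a, b, c, d)
with the variant-bearing grouping always "exposed",
log OR = ln(ad/bc), SE = √(1/a + 1/b + 1/c + 1/d). Any zero cell
triggers the Haldane–Anscombe correction (0.5 added to all four cells);
a margin empty in the raw table leaves the OR undefined. The allelic
model counts alleles, so its margins are twice the subject counts. ORs
below 1 read as protective; the variant allele orientation is declared
by the input and never inferred from frequency, because orientation
flips silently invert conclusions.

Pooling is inverse-variance on the log-OR scale. Heterogeneity is
Cochran's Q at fixed-effect weights, I² = max(0, (Q−df)/Q)·100, and the
DerSimonian–Laird moment estimate τ² = max(0, (Q−df)/C) with
C = Σw − Σw²/Σw. The switching rule uses the fixed-effect model iff
p(Q) > 0.1 **and** I² < 50 %, otherwise DL random effects; both
boundaries are strict, so I² exactly 50 pools as random. An
inverse-variance fixed effect (rather than Mantel–Haenszel) keeps one
canonical Q driving the rule; with Mantel–Haenszel the Q feeding the
rule and the Q of the estimator would differ.

Subgroup analyses pool each stratum with DL random effects by default
(the convention for between-subgroup testing; `pooling="rule"` applies
the switching rule per stratum instead) and compare strata with a Q test
on the stratum-level pooled effects. Meta-regression dummy-codes the
moderator, estimates residual τ² by method of moments from the
fixed-weight residual Q, and refits by weighted least squares — fully
deterministic and checkable by hand, unlike REML. Publication-bias
diagnostics (Egger regression of the standardized effect on precision;
Begg rank correlation of standardized deviates with variances, tau-b)
are computed only with k ≥ 10 studies; below that they are reported as
not applicable rather than as unreliable numbers.

## Bayesian network meta-analysis

Each study contributes three genotype arms with a binomial
case-membership outcome (events = cases with the genotype, trials = all
subjects carrying it — valid under case-control sampling because only
odds ratios are interpreted, never the baseline logits). The model is

    y_ig ~ Binomial(n_ig, p_ig),  logit(p_ig) = μ_i + δ_ig,
    δ_i,11 = 0,  δ_ig ~ Normal(d_g, τ²)  for g ∈ {12, 22},  d_11 = 0.

Priors: Normal(0, 10²) on μ_i and d_g (vague on the logit scale),
half-Normal(0, 1) on τ — between-study SDs of log-ORs above ~2 are
implausible in this literature. Genotype nodes define the network
rather than the six overlapping dichotomizations, which would count the
same subjects in several nodes; the composite models are instead derived
per posterior draw from (d_12, d_22) and the pooled control genotype
mix by the odds-tilting construction (case genotype odds ∝ control
probabilities × exp(d_g)).

Sampling is Metropolis-within-Gibbs with numpy-vectorized random-walk
updates for the μ's and δ's (all conditionally independent), a conjugate
Gibbs draw for d_g, and a log-scale random walk for τ; step sizes adapt
toward 44 % acceptance during burn-in only, so the retained chain is a
valid fixed-kernel chain. Defaults are 4 chains × 20,000 burn-in +
50,000 retained iterations; convergence is judged by the Gelman–Rubin
PSRF per basic parameter, with a warning attached above 1.1. Chains are
seeded through `numpy.random.SeedSequence.spawn`, so every run is
reproducible from one integer.

### Ranking criterion

SUCRA needs a per-draw ranking of the six models. Ranking by |log-OR|
alone is degenerate: nested dichotomizations can tie *exactly* — under a
purely recessive effect the recessive and homozygote contrasts are both
ln ψ, because only genotype 22 is tilted — and ties then resolve by
numerical noise. The default criterion therefore ranks by
information-weighted association strength: per draw,
|log OR| / SE₁(model), where SE₁ is the Woolf SE of the model's implied
2×2 at unit per-group sample size (control mix for controls, the draw's
implied case mix for cases). This encodes that a dichotomization is
"suitable for risk prediction" when its contrast is both strong and
precisely estimable in the population at hand: a model that discards
subjects (homozygote, heterozygote) or isolates a tiny group pays its
information price. Plain |log-OR| ranking remains available
(`criterion="abs_logor"`). SUCRA itself is
Σ_{r<K} CumP(r) / (K−1); its mean over models is exactly 0.5 for any
valid rank matrix, which the tests assert.

## Thakkinstian's algorithm

"OR = 1" is judged by the 95 % CI containing 1 and "≠ 1" by excluding it
(α = 0.05, configurable); the reciprocal condition OR2 = 1/OR3 is a
z-test of log OR2 + log OR3 against 0; the codominant inequality chains
use point estimates under all-significant conditions. Rules are checked
in the order recessive → dominant → complete over-dominant → codominant,
first match wins, otherwise undetermined. OR3 (22 vs 12) is pooled from
per-study tables, not derived algebraically from OR1/OR2, since the
per-study contrast is the quantity the algorithm calls for. When the
verdicts feed the candidate intersection, recessive/dominant/complete
over-dominant map to their namesake dichotomizations; codominant (a
dose-response claim with no single counterpart among the six) maps to
the allele-dose contrasts {allelic, homozygote}.

## FPRP

FPRP = α(1−π) / [α(1−π) + (1−β)π] with α the observed two-sided p and
1−β = Φ(δ/SE − z*) + Φ(−δ/SE − z*) the power to detect δ = |ln 1.5| at
critical value z*. The default sets z* equal to the observed z (the
spreadsheet convention of an α level equal to the observed p), which
reproduces published FPRP tables from printed OR/CI pairs to three
decimals; a fixed-α variant (z* = z_{0.975}) is exposed. Protective
effects are handled through |ln OR| — testing OR against 1.5 or 1/1.5 is
identical. Noteworthiness is FPRP < 0.2 at π = 0.01; the full per-prior
map (0.1 … 10⁻⁵) is always emitted so stricter readings remain
recoverable. A null effect (log OR = 0) yields α = 1 and a finite FPRP
limit, never NaN.

## Diagnostic meta-analysis

The risk-grouping 2×2 doubles as a diagnostic table, so DOR ≡ OR
exactly (asserted as a cross-module identity test). Sensitivity and
specificity pool on the logit scale — bounded and variance-stabilized,
unlike raw proportions — and the DOR on the log scale, all under the
same switching rule. The Moses–Littenberg fit D = a + bS uses unweighted
least squares (the classical default); AUC integrates the implied
TPR(FPR) curve by midpoint quadrature over the full unit interval
(2,000 points; doubling changes AUC by < 10⁻⁴), with an optional
seeded bootstrap over studies for its SE. Degenerate S variance (a
single threshold) forces the symmetric b = 0 curve with a warning. The
Spearman threshold test uses an exact permutation p-value for k ≤ 9 and
the t approximation above.

## Synthetic corpora

The generator draws control genotypes from exact HWE proportions at the
chosen variant-allele frequency and tilts them into case distributions
with per-genotype odds multipliers (recessive (1, 1, ψ); dominant
(1, ψ, ψ); over-dominant (1, ψ, 1); allelic (1, ψ, ψ²); codominant
(1, ψ^h, ψ), h = 0.5 by default). The tilting is exact for case-control
sampling, so the generating contrast's population OR equals ψ by
construction and recovery tests are sharp. Per-study ORs vary around the
truth with log-normal heterogeneity (SD τ); defaults — 10 studies,
150–1,200 subjects per group, MAF 0.3, τ = 0.1, a 72/28 Asian/Caucasian
split — mirror the shape of a typical SNP-association literature
(tens of studies of a few hundred to a couple of thousand subjects,
predominantly Asian cohorts).

What the generator does *not* emulate: genotyping error, HWE violations
in controls (departures arise only from sampling noise, so ~5 % of
simulated studies fail the screen at α = 0.05 by construction),
selective publication, covariate confounding, linkage disequilibrium
between SNPs, or real between-ethnicity effect differences unless
configured. Passing recovery tests therefore demonstrates correctness
of the statistical machinery under the stated model, not robustness to
those real-data pathologies.

## Benchmark problem sizes

The recovery benchmarks use deliberately moderate sizes chosen to give
sharp but quick checks: pairwise/decision recovery uses 50 corpora of
10 studies × (1,000 + 1,000) subjects at ψ = 1.6, τ = 0.05; NMA
model-recovery uses 50 corpora of 8 studies × (800 + 800) at ψ = 2.0
with 2 chains × (2,000 burn-in + 3,000 retained) draws, which the PSRF
gate shows is ample for this three-node model; CI-coverage uses 500
homogeneous corpora. Full-size NMA defaults (4 × 70,000) remain the
production setting.

## Known limitations

- The Moses–Littenberg SROC and DL random effects are the classical
  procedures this pipeline standardizes on; bivariate (Reitsma) and
  HSROC models, REML heterogeneity estimation and Hartung–Knapp
  adjustments are the stronger modern choices and are deliberately out
  of scope.
- The NMA assumes a shared τ² for both genotype effects and ignores
  within-study correlation between the 12 and 22 arms (they share no
  subjects, but do share the study baseline through μ_i, which is
  modeled).
- Ethnicity labels outside the literal {Asian, Caucasian, Other} are
  mapped to Other with a warning rather than guessed from ethnonyms;
  stratum membership is treated as a curation decision.
- With fewer than ~4 studies the DL τ² estimate is noisy and the
  switching rule effectively defaults to fixed effects unless
  heterogeneity is extreme; decisions on 2-study strata rest mostly on
  the FPRP gate.
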