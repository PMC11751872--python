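"""End-to-end orchestration: screen -> contrasts -> pairwise -> NMA ->
selection -> diagnostics, with a reproducible report bundle on disk.

Every stage writes plain-text tables (CSV/JSON) into the output
directory, and a run manifest records the configuration, seed, package
version and per-stage wall times so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contrasts import (GeneticModel, build_contrast, build_or3_contrast,
                        estimate_or)
from .diagnostics import (DiagnosticStudy, pool_accuracy, spearman_threshold,
                          sroc_moses)
from .errors import (DegenerateTableError, InsufficientStudiesError,
                     PipelineError)
from .network import NmaConfig, arm_counts, fit_nma, rank_models
from .pairwise import (bias_tests, choose_and_pool, leave_one_out,
                       subgroup_analysis)
from .selection import (DEFAULT_PRIORS, DEFAULT_THRESHOLD_OR,
                        ThakkinstianInput, decide, fprp, pick_nma_best,
                        thakkinstian_decide)
from .studies import (FilterConfig, GenotypeStudy, apply_inclusion_filters,
                      parse_studies)

logger = logging.getLogger(__name__)

STRATA = ("overall", "Asian", "Caucasian")


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run.

    The defaults reproduce the reference analysis settings: FPRP
    threshold OR 1.5 with priors (0.1, 0.01, 1e-3, 1e-4, 1e-5), and an
    NMA of 4 chains with 20,000 burn-in and 50,000 retained iterations.
    """

    out_dir: str = "snpmeta_out"
    strata: tuple = STRATA
    alpha: float = 0.05
    filters: FilterConfig = FilterConfig()
    run_nma: bool = True
    nma_chains: int = 4
    nma_burn_in: int = 20000
    nma_iterations: int = 50000
    fprp_threshold_or: float = DEFAULT_THRESHOLD_OR
    fprp_priors: tuple = DEFAULT_PRIORS
    diagnose_all: bool = False
    seed: int = 0


def _pool_models(studies, alpha):
    """choose_and_pool every genetic model; returns model -> PooledResult."""
    pooled = {}
    for model in GeneticModel:
        effects = []
        for s in studies:
            try:
                table = build_contrast(s.case_counts, s.control_counts, model)
                effects.append(estimate_or(table, label=s.study_id))
            except DegenerateTableError:
                logger.warning("study %s: degenerate %s table skipped",
                               s.study_id, model.value)
        if len(effects) >= 2:
            pooled[model] = choose_and_pool(effects).relabel(model=model), effects
    return pooled


def _thakkinstian(studies, alpha):
    effects3 = []
    for s in studies:
        try:
            effects3.append(estimate_or(
                build_or3_contrast(s.case_counts, s.control_counts),
                label=s.study_id))
        except DegenerateTableError:
            pass
    if len(effects3) < 2:
        return None
    or3 = choose_and_pool(effects3).effect
    return or3


def analyze_stratum(snp_id: str, stratum: str,
                    studies: Sequence[GenotypeStudy],
                    config: RunConfig) -> dict:
    """All analysis stages for one (SNP, stratum) study set."""
    out: dict = {"snp_id": snp_id, "stratum": stratum, "k": len(studies)}
    if len(studies) < 2:
        out["skipped"] = "fewer than 2 studies"
        return out

    pooled = _pool_models(studies, config.alpha)
    out["pooled"] = {m: p for m, (p, _e) in pooled.items()}
    out["effects"] = {m: e for m, (_p, e) in pooled.items()}
    significant = {m: p.effect for m, (p, _e) in pooled.items()
                   if p.effect.p_value < config.alpha}
    out["significant"] = significant

    # sensitivity / subgroup / bias on the recessive-to-allelic suite
    loo = {}
    for m, (_p, effects) in pooled.items():
        if len(effects) >= 3:
            loo[m] = leave_one_out(effects)
    out["leave_one_out"] = loo

    subgroups = {}
    if stratum == "overall":
        eth = [s.ethnicity for s in studies]
        for m, (_p, effects) in pooled.items():
            if len(set(eth)) >= 2:
                subgroups[(m, "ethnicity")] = subgroup_analysis(effects, eth)
    methods = [s.genotyping_method for s in studies]
    for m, (_p, effects) in pooled.items():
        if len(set(methods)) >= 2:
            subgroups[(m, "genotyping_method")] = subgroup_analysis(
                effects, methods)
    out["subgroups"] = subgroups

    out["bias"] = {m: bias_tests(effects)
                   for m, (_p, effects) in pooled.items()}

    # Thakkinstian's algorithm on OR1/OR2/OR3
    verdict = None
    if (GeneticModel.HOMOZYGOTE in pooled
            and GeneticModel.HETEROZYGOTE in pooled):
        or3 = _thakkinstian(studies, config.alpha)
        if or3 is not None:
            inp = ThakkinstianInput(
                or1=pooled[GeneticModel.HOMOZYGOTE][0].effect,
                or2=pooled[GeneticModel.HETEROZYGOTE][0].effect,
                or3=or3)
            verdict = thakkinstian_decide(inp, alpha=config.alpha)
    out["thakkinstian"] = verdict

    # Bayesian NMA + SUCRA
    nma_best = None
    if config.run_nma:
        events, trials = arm_counts(studies)
        nma_cfg = NmaConfig(chains=config.nma_chains,
                            burn_in=config.nma_burn_in,
                            iterations=config.nma_iterations,
                            seed=config.seed)
        post = fit_nma(events, trials, nma_cfg)
        ctrl_totals = np.array([s.control_counts for s in studies],
                               dtype=float).sum(axis=0)
        models, probs, scores = rank_models(post, ctrl_totals)
        nma_best = pick_nma_best(models, scores, verdict)
        out["nma"] = {"models": models, "rank_probs": probs,
                      "sucra": scores, "psrf": post.psrf,
                      "warnings": post.warnings}
    out["nma_best"] = nma_best

    # FPRP on every significant model, then the composite decision
    fprp_results = {
        m: fprp(e, threshold_or=config.fprp_threshold_or,
                priors=config.fprp_priors)
        for m, e in significant.items()}
    out["fprp"] = fprp_results
    if verdict is None:
        from .selection import ModelVerdict
        verdict = ModelVerdict("undetermined", "insufficient contrasts")
    decision = decide(
        snp_id=snp_id, stratum=stratum, k=len(studies),
        significant=significant, thakkinstian=verdict,
        fprp_results=fprp_results, nma_best=nma_best,
        pooled_or={m: p.effect.odds_ratio
                   for m, (p, _e) in pooled.items()})
    out["decision"] = decision

    # diagnostic meta-analysis for definitive (hazardous) models
    diag = {}
    targets = decision.definitive if not config.diagnose_all else set(pooled)
    for m in targets:
        if not config.diagnose_all and decision.direction != "hazardous":
            continue
        dstudies = [DiagnosticStudy.from_two_by_two(
            build_contrast(s.case_counts, s.control_counts, m))
            for s in studies]
        entry = {"pooled": pool_accuracy(dstudies)}
        if len(dstudies) >= 3:
            entry["sroc"] = sroc_moses(dstudies, n_boot=200,
                                       seed=config.seed)
            entry["spearman"] = spearman_threshold(dstudies)
        diag[m] = entry
    out["diagnostics"] = diag
    return out


def _pooled_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        for m, p in res.get("pooled", {}).items():
            e, h = p.effect, p.het
            rows.append({
                "snp_id": res["snp_id"], "stratum": res["stratum"],
                "model": m.value, "k": p.k, "method": p.method,
                "or": e.odds_ratio, "ci_low": e.ci_low,
                "ci_high": e.ci_high, "p": e.p_value,
                "q": h.q, "p_q": h.p_q, "i2": h.i2, "tau2": h.tau2,
            })
    return pd.DataFrame(rows)


def run_pipeline(studies: Sequence[GenotypeStudy],
                 config: RunConfig = RunConfig()) -> dict:
    """Run every stage over a screened corpus and write the bundle.

    Returns a dict of in-memory results keyed by (snp, stratum); all
    tables are also written under ``config.out_dir``.  If screening
    leaves no studies, only the screening report is written and
    PipelineError is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.perf_counter()

    screen = apply_inclusion_filters(studies, config.filters)
    screen.write(out_dir / "screening.csv", out_dir / "screening.json")
    timings["screen"] = time.perf_counter() - t0

    if not screen.kept:
        _write_manifest(out_dir, config, timings,
                        error="all studies filtered out")
        raise PipelineError("all studies were filtered out during screening")

    by_snp: dict[str, list[GenotypeStudy]] = {}
    for s in screen.kept:
        by_snp.setdefault(s.snp_id, []).append(s)

    results = []
    t1 = time.perf_counter()
    for snp_id, snp_studies in sorted(by_snp.items()):
        for stratum in config.strata:
            if stratum == "overall":
                subset = snp_studies
            else:
                subset = [s for s in snp_studies if s.ethnicity == stratum]
                # skip empty strata and strata identical to the overall set
                if not subset or len(subset) == len(snp_studies):
                    continue
            results.append(analyze_stratum(snp_id, stratum, subset, config))
    timings["analysis"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    _pooled_frame(results).to_csv(out_dir / "pooled.csv", index=False)

    decision_rows = [res["decision"].to_row() for res in results
                     if "decision" in res]
    pd.DataFrame(decision_rows).to_csv(out_dir / "decisions.csv", index=False)
    (out_dir / "decisions.json").write_text(
        json.dumps(decision_rows, indent=2))

    sucra_rows = []
    for res in results:
        if "nma" in res:
            for m, s in zip(res["nma"]["models"], res["nma"]["sucra"]):
                sucra_rows.append({
                    "snp_id": res["snp_id"], "stratum": res["stratum"],
                    "model": m.value, "sucra": float(s)})
    if sucra_rows:
        pd.DataFrame(sucra_rows).to_csv(out_dir / "sucra.csv", index=False)

    diag_rows = []
    for res in results:
        for m, entry in res.get("diagnostics", {}).items():
            pa = entry["pooled"]
            row = {"snp_id": res["snp_id"], "stratum": res["stratum"],
                   "model": m.value, "sens": pa.sens.value,
                   "spec": pa.spec.value, "plr": pa.plr.value,
                   "nlr": pa.nlr.value, "dor": pa.dor.value,
                   "dor_ci_low": pa.dor.ci_low, "dor_ci_high": pa.dor.ci_high}
            if "sroc" in entry:
                row["sroc_auc"] = entry["sroc"].auc
                row["sroc_se_auc"] = entry["sroc"].se_auc
                row["spearman_rho"] = entry["spearman"][0]
                row["spearman_p"] = entry["spearman"][1]
            diag_rows.append(row)
    if diag_rows:
        pd.DataFrame(diag_rows).to_csv(out_dir / "diagnostics.csv",
                                       index=False)
    timings["reports"] = time.perf_counter() - t2

    _write_manifest(out_dir, config, timings)
    return {"screen": screen, "results": results}


def run_from_csv(path, config: RunConfig = RunConfig()) -> dict:
    report = parse_studies(path)
    if report.row_errors:
        logger.warning("%d rows rejected during parsing",
                       len(report.row_errors))
    return run_pipeline(report.studies, config)


def _write_manifest(out_dir: Path, config: RunConfig, timings: dict,
                    error: Optional[str] = None) -> None:
    cfg = dataclasses.asdict(config)
    cfg["filters"] = dataclasses.asdict(config.filters)
    manifest = {
        "snpmeta_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "stage_seconds": timings,
    }
    if error:
        manifest["error"] = error
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
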