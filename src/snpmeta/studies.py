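"""Reading, validating and screening per-study genotype data.

One record per (study, SNP): case and control genotype count triples plus
the metadata the downstream analyses stratify on (ethnicity, control
source, genotyping method, quality score).  Screening applies the three
computable inclusion filters: control Hardy-Weinberg conformity, total
sample size >= 300, and methodological quality score >= 7 on the 15-point
scale (scores >= 11 are "high" quality, 7-10 "medium", < 7 excluded).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .errors import RowError, SchemaError, UndefinedInputError

logger = logging.getLogger(__name__)

ETHNICITIES = ("Asian", "Caucasian", "Other")
CONTROL_SOURCES = ("population", "hospital", "unknown")
GENOTYPING_METHODS = ("RFLP-PCR", "TaqMan", "Other")

# Documented ethnicity mapping table.  Only the literal stratum names
# (case-insensitive) are recognized; every other label -- including
# specific ethnonyms such as "Han Chinese" -- maps to Other with a
# warning, because stratum membership is a curation decision, not one to
# be inferred from free text.  Only Asian and Caucasian form subgroups.
_ETHNICITY_MAP = {
    "asian": "Asian",
    "caucasian": "Caucasian",
    "other": "Other",
}

_GENOTYPING_MAP = {
    "rflp-pcr": "RFLP-PCR", "pcr-rflp": "RFLP-PCR", "rflp": "RFLP-PCR",
    "taqman": "TaqMan", "other": "Other", "others": "Other",
}

_CONTROL_SOURCE_MAP = {
    "population": "population", "population-based": "population",
    "pb": "population", "hospital": "hospital", "hospital-based": "hospital",
    "hb": "hospital", "unknown": "unknown", "": "unknown",
}

REQUIRED_COLUMNS = (
    "study_id", "snp_id", "case_11", "case_12", "case_22",
    "ctrl_11", "ctrl_12", "ctrl_22",
)
OPTIONAL_COLUMNS = (
    "gene", "ethnicity", "control_source", "genotyping_method",
    "quality_total", "first_author", "year", "country",
)


def normalize_ethnicity(label: str) -> str:
    """Map a free-text ethnicity label to Asian / Caucasian / Other.

    Unknown labels map to Other with a logged warning; Other-stratum
    studies contribute to overall pooling but not to ethnicity subgroups.
    """
    key = str(label).strip().lower()
    if key in _ETHNICITY_MAP:
        return _ETHNICITY_MAP[key]
    logger.warning("ethnicity %r not recognized; mapped to Other", label)
    return "Other"


def normalize_genotyping_method(label: str) -> str:
    return _GENOTYPING_MAP.get(str(label).strip().lower(), "Other")


def normalize_control_source(label: str) -> str:
    return _CONTROL_SOURCE_MAP.get(str(label).strip().lower(), "unknown")


@dataclass
class GenotypeStudy:
    """One study's genotype counts for one SNP, plus metadata.

    Counts are ordered (n11, n12, n22) = (common homozygote, heterozygote,
    variant homozygote); allele "2" is the variant allele as declared by
    the input, never inferred from frequency.
    """

    study_id: str
    snp_id: str
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]
    gene: str = ""
    ethnicity: str = "Other"
    control_source: str = "unknown"
    genotyping_method: str = "Other"
    quality_total: Optional[int] = None

    def __post_init__(self):
        self.case_counts = tuple(int(c) for c in self.case_counts)
        self.control_counts = tuple(int(c) for c in self.control_counts)
        if any(c < 0 for c in self.case_counts + self.control_counts):
            raise ValueError("genotype counts must be non-negative")
        if self.case_total < 1 or self.control_total < 1:
            raise ValueError("case and control totals must be >= 1")
        if self.ethnicity not in ETHNICITIES:
            self.ethnicity = normalize_ethnicity(self.ethnicity)
        if self.genotyping_method not in GENOTYPING_METHODS:
            self.genotyping_method = normalize_genotyping_method(
                self.genotyping_method)
        if self.control_source not in CONTROL_SOURCES:
            self.control_source = normalize_control_source(self.control_source)

    @property
    def case_total(self) -> int:
        return sum(self.case_counts)

    @property
    def control_total(self) -> int:
        return sum(self.control_counts)

    @property
    def total(self) -> int:
        return self.case_total + self.control_total

    def to_row(self) -> dict:
        row = {
            "study_id": self.study_id, "snp_id": self.snp_id,
            "gene": self.gene, "ethnicity": self.ethnicity,
            "control_source": self.control_source,
            "genotyping_method": self.genotyping_method,
            "case_11": self.case_counts[0], "case_12": self.case_counts[1],
            "case_22": self.case_counts[2], "ctrl_11": self.control_counts[0],
            "ctrl_12": self.control_counts[1], "ctrl_22": self.control_counts[2],
            "quality_total": self.quality_total,
        }
        return row


@dataclass(frozen=True)
class HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions."""

    chi2: float
    p_value: float
    conforms: bool
    degenerate: bool = False


@dataclass(frozen=True)
class QualityClass:
    """Classification on the 15-point methodological quality scale."""

    total_score: int
    label: str  # "high" | "medium" | "excluded"

    @classmethod
    def from_score(cls, score: int) -> "QualityClass":
        score = int(score)
        if not 0 <= score <= 15:
            raise ValueError(f"quality score must be in 0..15, got {score}")
        if score >= 11:
            label = "high"
        elif score >= 7:
            label = "medium"
        else:
            label = "excluded"
        return cls(total_score=score, label=label)


def variant_allele_frequency(counts: Sequence[int]) -> float:
    """Frequency of the declared variant allele: (2*n22 + n12) / (2*N)."""
    n11, n12, n22 = counts
    total = n11 + n12 + n22
    if total <= 0:
        raise UndefinedInputError("allele frequency undefined for zero total")
    return (2 * n22 + n12) / (2 * total)


def hwe_test(control_counts: Sequence[int], alpha: float = 0.05) -> HweResult:
    """Pearson chi-square (1 df) test of HWE on a genotype count triple.

    Expected counts come from the estimated allele frequency; conforms
    means p >= alpha.  A monomorphic triple (variant or common allele
    absent) is flagged degenerate and conforms by convention.
    """
    n11, n12, n22 = (int(c) for c in control_counts)
    total = n11 + n12 + n22
    if total <= 0:
        raise UndefinedInputError("HWE test undefined for zero total")
    q = (2 * n22 + n12) / (2 * total)
    if q == 0.0 or q == 1.0:
        return HweResult(chi2=0.0, p_value=1.0, conforms=True, degenerate=True)
    expected = (total * (1 - q) ** 2, total * 2 * q * (1 - q), total * q ** 2)
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n11, n12, n22), expected))
    p = float(chi2_dist.sf(chi2, df=1))
    return HweResult(chi2=float(chi2), p_value=p, conforms=p >= alpha)


@dataclass
class ParseReport:
    """Outcome of parsing a genotype CSV: records plus row diagnostics."""

    studies: list[GenotypeStudy] = field(default_factory=list)
    row_errors: list[RowError] = field(default_factory=list)


def parse_studies(path, schema: Optional[dict] = None) -> ParseReport:
    """Read per-(study, SNP) genotype rows from a delimited text file.

    Parameters
    ----------
    path : CSV file, one row per (study, SNP).
    schema : optional map from canonical column names (``study_id``,
        ``case_11``, ...) to the file's column names.

    Rows with missing, negative or non-integer counts are rejected with a
    RowError naming the offending cell; valid rows are kept.  A missing
    required column raises SchemaError.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    count_cols = ("case_11", "case_12", "case_22",
                  "ctrl_11", "ctrl_12", "ctrl_22")
    report = ParseReport()
    for i, row in enumerate(df.itertuples(index=False)):
        rec = row._asdict()
        counts = {}
        bad = None
        for col in count_cols:
            raw = str(rec[col]).strip()
            try:
                val = int(raw)
            except ValueError:
                bad = RowError(i, col, f"count {raw!r} is not an integer")
                break
            if val < 0:
                bad = RowError(i, col, f"count {val} is negative")
                break
            counts[col] = val
        if bad is not None:
            report.row_errors.append(bad)
            continue
        quality = rec.get("quality_total", "")
        quality_total = int(quality) if str(quality).strip() else None
        try:
            study = GenotypeStudy(
                study_id=str(rec["study_id"]),
                snp_id=str(rec["snp_id"]),
                gene=str(rec.get("gene", "")),
                ethnicity=str(rec.get("ethnicity", "Other")),
                control_source=str(rec.get("control_source", "unknown")),
                genotyping_method=str(rec.get("genotyping_method", "Other")),
                case_counts=(counts["case_11"], counts["case_12"],
                             counts["case_22"]),
                control_counts=(counts["ctrl_11"], counts["ctrl_12"],
                                counts["ctrl_22"]),
                quality_total=quality_total,
            )
        except ValueError as exc:
            report.row_errors.append(RowError(i, "counts", str(exc)))
            continue
        report.studies.append(study)
    return report


def write_studies(studies: Iterable[GenotypeStudy], path) -> None:
    """Serialize records to the same CSV schema parse_studies consumes."""
    pd.DataFrame([s.to_row() for s in studies]).to_csv(path, index=False)


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the computable inclusion filters."""

    alpha_hwe: float = 0.05
    min_sample_size: int = 300
    min_quality: int = 7


@dataclass
class ScreenResult:
    """Kept/dropped split with per-study drop reasons and screening stats."""

    kept: list[GenotypeStudy]
    dropped: list[tuple[GenotypeStudy, str]]
    hwe: dict  # (study_id, snp_id) -> HweResult
    maf: dict  # (study_id, snp_id) -> control variant-allele frequency
    underreported_snps: list[str]  # SNPs retained in < 2 studies

    def to_frame(self) -> pd.DataFrame:
        rows = []
        reasons = {(s.study_id, s.snp_id): r for s, r in self.dropped}
        for s in self.kept + [s for s, _ in self.dropped]:
            key = (s.study_id, s.snp_id)
            hwe = self.hwe[key]
            rows.append({
                "study_id": s.study_id, "snp_id": s.snp_id,
                "ethnicity": s.ethnicity, "total": s.total,
                "hwe_chi2": hwe.chi2, "hwe_p": hwe.p_value,
                "control_maf": self.maf[key],
                "quality_total": s.quality_total,
                "kept": key not in reasons,
                "drop_reason": reasons.get(key, ""),
            })
        return pd.DataFrame(rows)

    def write(self, csv_path, json_path=None) -> None:
        frame = self.to_frame()
        frame.to_csv(csv_path, index=False)
        if json_path is not None:
            payload = {
                "n_kept": len(self.kept),
                "n_dropped": len(self.dropped),
                "underreported_snps": self.underreported_snps,
                "alpha_hwe_note": "HWE conformity judged at the configured "
                                  "alpha (default 0.05)",
                "rows": frame.to_dict(orient="records"),
            }
            Path(json_path).write_text(json.dumps(payload, indent=2))


def apply_inclusion_filters(studies: Sequence[GenotypeStudy],
                            config: FilterConfig = FilterConfig()
                            ) -> ScreenResult:
    """Apply the computable inclusion filters to a study set.

    A study is dropped when its controls violate HWE at ``alpha_hwe``,
    its case+control total is below ``min_sample_size``, or its quality
    score classifies as excluded (< ``min_quality``).  The first failing
    filter (HWE, then size, then quality) is recorded as the reason; the
    kept set is independent of filter order.  SNPs retained by fewer than
    two studies are flagged as underreported.
    """
    kept, dropped = [], []
    hwe_map, maf_map = {}, {}
    for s in studies:
        key = (s.study_id, s.snp_id)
        hwe = hwe_test(s.control_counts, alpha=config.alpha_hwe)
        hwe_map[key] = hwe
        maf_map[key] = variant_allele_frequency(s.control_counts)
        if not hwe.conforms:
            dropped.append((s, "HWE violation in controls"))
        elif s.total < config.min_sample_size:
            dropped.append((s, "sample size"))
        elif s.quality_total is not None and s.quality_total < config.min_quality:
            dropped.append((s, "quality"))
        else:
            kept.append(s)
    counts: dict[str, int] = {}
    for s in kept:
        counts[s.snp_id] = counts.get(s.snp_id, 0) + 1
    underreported = sorted(snp for snp, n in counts.items() if n < 2)
    return ScreenResult(kept=kept, dropped=dropped, hwe=hwe_map,
                        maf=maf_map, underreported_snps=underreported)
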