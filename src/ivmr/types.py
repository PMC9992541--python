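"""Core data model for two-sample Mendelian randomization.

The package works on GWAS *summary statistics*: one association record per
variant per trait. Exposure effects are per 1 SD of the (continuous) trait;
outcome effects are log odds ratios from a case-control GWAS. Everything
downstream — harmonization, the estimator suite, the sensitivity analyses —
consumes the containers defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement_allele(allele: str) -> str:
    """Watson-Crick complement of a single-base allele."""
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be resolved from alleles."""
    return _COMPLEMENT.get(a1) == a2


@dataclass
class VariantAssociation:
    """One variant's association with one trait in one GWAS.

    ``beta`` is per effect-allele copy: per SD of the trait for a continuous
    exposure, log odds for a binary outcome. ``eaf`` is the effect allele
    frequency.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int | None = None
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def violations(self) -> list[str]:
        """Invariant violations, empty when the record is analysis-ready."""
        problems: list[str] = []
        if self.effect_allele not in VALID_ALLELES:
            problems.append(f"effect_allele {self.effect_allele!r} is not a single-base SNP allele")
        if self.other_allele not in VALID_ALLELES:
            problems.append(f"other_allele {self.other_allele!r} is not a single-base SNP allele")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if not (math.isfinite(self.beta)):
            problems.append("beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            problems.append("se must be finite and > 0")
        if not (0 < self.pval <= 1):
            problems.append("pval must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            problems.append("eaf must be in [0, 1]")
        return problems

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def flipped(self) -> "VariantAssociation":
        """The same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


_SUMSTAT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]


@dataclass
class SummaryTable:
    """An ordered collection of variant associations for one trait."""

    trait_label: str
    records: list[VariantAssociation] = field(default_factory=list)
    trait_type: str = "continuous"  # continuous | binary
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate snp_id in {self.trait_label}: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def get(self, snp_id: str) -> VariantAssociation | None:
        for r in self.records:
            if r.snp_id == snp_id:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(r, c) for c in _SUMSTAT_COLUMNS}
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=_SUMSTAT_COLUMNS)

    def with_records(self, records: list[VariantAssociation]) -> "SummaryTable":
        return SummaryTable(
            trait_label=self.trait_label,
            records=list(records),
            trait_type=self.trait_type,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
        )


@dataclass
class LDMatrix:
    """Squared-correlation matrix over a set of variants (diagonal exactly 1)."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal must be exactly 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("LD r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, snp_ids: list[str]) -> "LDMatrix":
        return cls(snp_ids=list(snp_ids), r2=np.eye(len(snp_ids)))


@dataclass
class InstrumentConfig:
    """Thresholds governing instrument selection and LD clumping.

    Defaults are the conventional genome-wide settings: p < 5e-8,
    MAF >= 1%, clumping at r2 < 0.001 within a 10 Mb window, and proxies
    accepted at r2 > 0.8.
    """

    p_threshold: float = 5e-8
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_r2_min: float = 0.8
    drop_missing_eaf: bool = True  # strict mode: no EAF -> fails the MAF filter

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if not (0 <= self.proxy_r2_min <= 1):
            raise ValueError("proxy_r2_min must be in [0, 1]")


# ---------------------------------------------------------------------------
# Harmonized containers
# ---------------------------------------------------------------------------

KEPT_STATUSES = ("kept", "flipped", "strand_corrected")
DROPPED_STATUSES = ("dropped_palindromic", "dropped_incompatible")


@dataclass
class HarmonizedRecord:
    """Exposure and outcome effects for one variant on a common effect allele."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None
    eaf_y: float | None
    status: str
    effect_allele: str | None = None
    other_allele: str | None = None
    n_x: int | None = None
    n_y: int | None = None

    @property
    def kept(self) -> bool:
        return self.status in KEPT_STATUSES


@dataclass
class HarmonizedSet:
    """Instrument-aligned effect vectors — the substrate of every estimator.

    Only kept records enter the effect vectors; dropped records live in
    ``audit`` with their reason.
    """

    exposure_label: str
    outcome_label: str
    records: list[HarmonizedRecord]
    audit: list[HarmonizedRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [r.snp_id for r in self.records if not r.kept]
        if bad:
            raise ValueError(f"non-kept records in HarmonizedSet.records: {bad}")
        for r in self.records:
            if not (r.se_x > 0 and r.se_y > 0):
                raise ValueError(f"{r.snp_id}: kept record must have positive SEs")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_snps(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def _vec(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.records], dtype=float)

    @property
    def beta_x(self) -> np.ndarray:
        return self._vec("beta_x")

    @property
    def se_x(self) -> np.ndarray:
        return self._vec("se_x")

    @property
    def beta_y(self) -> np.ndarray:
        return self._vec("beta_y")

    @property
    def se_y(self) -> np.ndarray:
        return self._vec("se_y")

    @property
    def eaf_x(self) -> np.ndarray:
        return np.array(
            [np.nan if r.eaf_x is None else r.eaf_x for r in self.records], dtype=float
        )

    def subset(self, indices) -> "HarmonizedSet":
        idx = list(indices)
        return HarmonizedSet(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            records=[self.records[i] for i in idx],
            audit=list(self.audit),
        )

    def drop_snps(self, snp_ids) -> "HarmonizedSet":
        dropped = set(snp_ids)
        return HarmonizedSet(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            records=[r for r in self.records if r.snp_id not in dropped],
            audit=list(self.audit),
        )

    def to_frame(self, include_audit: bool = False) -> pd.DataFrame:
        rows = list(self.records) + (list(self.audit) if include_audit else [])
        return pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id,
                    "beta_x": r.beta_x,
                    "se_x": r.se_x,
                    "beta_y": r.beta_y,
                    "se_y": r.se_y,
                    "eaf_x": r.eaf_x,
                    "eaf_y": r.eaf_y,
                    "status": r.status,
                }
                for r in rows
            ]
        )


@dataclass
class MVMRSet:
    """Joint instrument matrix for multivariable MR: L SNPs x K exposures."""

    exposure_labels: list[str]
    snp_ids: list[str]
    beta_x: np.ndarray  # (L, K)
    se_x: np.ndarray    # (L, K)
    beta_y: np.ndarray  # (L,)
    se_y: np.ndarray    # (L,)
    audit: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        L, K = self.beta_x.shape
        if K < 2:
            raise ValueError("MVMR requires at least two exposures")
        if len(set(self.exposure_labels)) != K:
            raise ValueError("collinear exposure labels: duplicates in exposure_labels")
        if self.se_x.shape != (L, K) or self.beta_y.shape != (L,) or self.se_y.shape != (L,):
            raise ValueError("MVMRSet dimensions are inconsistent")
        if np.isnan(self.beta_x).any():
            raise ValueError("missing exposure beta for a kept SNP")
        if L < K + 1:
            raise ValueError(f"MVMR needs at least K+1={K + 1} SNPs, got {L}")

    @property
    def n_snps(self) -> int:
        return self.beta_x.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_x.shape[1]


# ---------------------------------------------------------------------------
# Estimate containers
# ---------------------------------------------------------------------------

@dataclass
class MREstimate:
    """A causal-effect estimate: log odds of outcome per 1 SD of exposure."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    exposure: str | None = None
    outcome: str | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    @classmethod
    def from_wald(cls, method: str, beta: float, se: float, n_snps: int,
                  df: int | None = None, **kw) -> "MREstimate":
        """Build from a point estimate and SE.

        Normal reference distribution by default; Student t with ``df``
        degrees of freedom when given (used for Egger's small-k regression).
        """
        if df is None:
            crit = stats.norm.ppf(0.975)
            pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
        else:
            crit = stats.t.ppf(0.975, df)
            pval = 2.0 * stats.t.sf(abs(beta) / se, df) if se > 0 else (1.0 if beta == 0 else 0.0)
        return cls(
            method=method, beta=float(beta), se=float(se),
            ci_low=float(beta - crit * se), ci_high=float(beta + crit * se),
            pval=float(pval), n_snps=n_snps, **kw,
        )


@dataclass
class EggerResult:
    """MR-Egger regression: slope (causal effect) plus pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float
    i2_gx: float | None = None
    simex_applied: bool = False


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity of per-variant causal estimates."""

    Q: float
    df: int
    pval: float
    i2: float

    @property
    def band(self) -> str:
        """Qualitative heterogeneity band on the conventional I2 cut-points."""
        pct = 100.0 * self.i2
        if pct < 25:
            return "none"
        if pct < 50:
            return "low"
        if pct < 75:
            return "moderate"
        return "substantial"


@dataclass
class StrengthResult:
    """Instrument-strength metrics: per-SNP variance explained and F."""

    snp_ids: list[str]
    per_snp_r2: np.ndarray
    per_snp_f: np.ndarray
    total_r2: float
    mean_f: float
    excluded: list[str] = field(default_factory=list)


@dataclass
class PressoResult:
    """MR-PRESSO global, per-SNP outlier, and distortion test results."""

    global_rss: float
    global_p: float
    outlier_pvals: np.ndarray
    outliers: list[int]
    outlier_snp_ids: list[str]
    distortion_p: float | None
    raw_estimate: MREstimate
    adjusted_estimate: MREstimate | None


@dataclass
class PowerParams:
    """Inputs for binary-outcome MR power at a given assumed causal OR."""

    n_cases: int
    n_controls: int
    r2: float
    true_or: float = 1.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.r2 < 1):
            raise ValueError("r2 must be in [0, 1)")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
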