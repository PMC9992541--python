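"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the summary-data setting directly: per-SNP exposure
effects gamma_j are drawn from a configurable distribution, sampling SEs
follow the standard 1/sqrt(2 p (1-p) N) approximation for a standardized
continuous trait, and outcome effects on the log-odds scale are
theta * gamma_j plus an optional direct (pleiotropic) effect alpha_j, with
the case-control SE approximation 1/sqrt(2 p (1-p) N K (1-K)). Correlation
between alpha_j and gamma_j is configurable so violations of the InSIDE
condition can be produced on demand. No individual-level genotypes are
simulated.

Default sample sizes mirror a large published setting for this design: a
22,393-individual exposure GWAS and a 33,674-case / 449,056-control outcome
GWAS, with a ``scale`` factor to shrink both for fast tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .types import LDMatrix, SummaryTable, VariantAssociation

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated two-sample study."""

    k_snps: int = 31
    n_exposure: int = 22_393
    n_cases: int = 33_674
    n_controls: int = 449_056
    scale: float = 1.0          # divide all sample sizes by this factor
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_mean: float | tuple = 0.15  # per-SD exposure effect (scalar or per-exposure)
    gamma_sd: float | tuple = 0.05
    theta: float = 0.0          # true causal log-odds per SD exposure
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_corr: float = 0.0    # corr(alpha_j, gamma_j); 0 = InSIDE holds
    n_exposures: int = 1        # >1 builds an MVMR scenario
    cross_effects: np.ndarray | None = None  # (K, K) exposure loading matrix
    seed: int = 0               # mandatory; identical seed -> identical study

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if np.any(np.asarray(self.gamma_sd) < 0) or self.pleiotropy_sd < 0:
            raise ValueError("sd parameters must be >= 0")
        if not (-1 <= self.inside_corr <= 1):
            raise ValueError("inside_corr must be in [-1, 1]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class SimulatedStudy:
    """Synthetic exposure/outcome tables plus the generating truth."""

    exposure_tables: list[SummaryTable]
    outcome_table: SummaryTable
    ld: LDMatrix
    theta: float
    gamma: np.ndarray           # (k, K) true exposure effects
    alpha: np.ndarray           # (k,) direct outcome effects
    outlier_indices: list[int] = field(default_factory=list)

    @property
    def exposure_table(self) -> SummaryTable:
        return self.exposure_tables[0]


def _make_table(label, snp_ids, alleles, maf, beta, se, n, trait_type="continuous",
                n_cases=None, n_controls=None) -> SummaryTable:
    z = beta / se
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)
    records = [
        VariantAssociation(
            snp_id=snp_ids[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            eaf=float(maf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pvals[j]),
            n=int(n),
            chrom="1",
            pos=1_000_000 * (j + 1),  # well past any clumping window
        )
        for j in range(len(snp_ids))
    ]
    return SummaryTable(
        trait_label=label, records=records, trait_type=trait_type,
        n_cases=n_cases, n_controls=n_controls,
    )


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Draw one two-sample study from the configured generating model.

    Identical configs (including seed) give bit-identical tables. The LD
    matrix is the identity: simulated instruments are independent by
    construction.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_snps
    K = cfg.n_exposures
    n_exp = max(2, round(cfg.n_exposure / cfg.scale))
    n_cases = max(1, round(cfg.n_cases / cfg.scale))
    n_controls = max(1, round(cfg.n_controls / cfg.scale))
    n_out = n_cases + n_controls
    case_frac = n_cases / n_out

    maf = rng.uniform(*cfg.maf_range, size=k)
    het = 2.0 * maf * (1.0 - maf)
    snp_ids = [f"rs{j + 1}" for j in range(k)]
    alleles = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(k)]

    g_mean = np.broadcast_to(np.asarray(cfg.gamma_mean, dtype=float), (K,))
    g_sd = np.broadcast_to(np.asarray(cfg.gamma_sd, dtype=float), (K,))
    gamma = rng.normal(g_mean[None, :], g_sd[None, :], size=(k, K))
    if K > 1:
        loadings = cfg.cross_effects if cfg.cross_effects is not None else np.eye(K)
        gamma = gamma @ np.asarray(loadings, dtype=float).T

    # direct (pleiotropic) effects, optionally correlated with gamma
    if cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0:
        z_indep = rng.normal(size=k)
        if g_sd[0] > 0 and cfg.inside_corr != 0:
            z_gamma = (gamma[:, 0] - g_mean[0]) / g_sd[0]
            z = cfg.inside_corr * z_gamma + np.sqrt(1 - cfg.inside_corr**2) * z_indep
        else:
            z = z_indep
        alpha = cfg.pleiotropy_mean + cfg.pleiotropy_sd * z
    else:
        alpha = np.zeros(k)

    se_x = 1.0 / np.sqrt(het * n_exp)
    exposure_tables = []
    beta_x_all = rng.normal(gamma, se_x[:, None])
    for m in range(K):
        exposure_tables.append(
            _make_table(
                f"exposure{m + 1}" if K > 1 else "exposure",
                snp_ids, alleles, maf, beta_x_all[:, m], se_x, n_exp,
            )
        )

    # causal effect flows through every exposure's gamma (theta per exposure
    # applies to the first exposure only unless cross_effects says otherwise)
    true_y = cfg.theta * gamma[:, 0] + alpha
    se_y = 1.0 / np.sqrt(het * n_out * case_frac * (1.0 - case_frac))
    beta_y = rng.normal(true_y, se_y)
    outcome = _make_table(
        "outcome", snp_ids, alleles, maf, beta_y, se_y, n_out,
        trait_type="binary", n_cases=n_cases, n_controls=n_controls,
    )

    return SimulatedStudy(
        exposure_tables=exposure_tables,
        outcome_table=outcome,
        ld=LDMatrix.identity(snp_ids),
        theta=cfg.theta,
        gamma=gamma,
        alpha=alpha,
    )


def inject_outlier(study: SimulatedStudy, index: int, multiplier: float) -> SimulatedStudy:
    """Add ``multiplier`` outcome-SEs of direct effect to one variant.

    Produces a horizontal-pleiotropy outlier of controlled magnitude; the
    truth record is updated so detection tests know the answer.
    """
    k = len(study.outcome_table)
    if not (0 <= index < k):
        raise IndexError(f"outlier index {index} out of range for {k} SNPs")
    rec = study.outcome_table.records[index]
    shifted = replace(rec, beta=rec.beta + multiplier * rec.se)
    z = shifted.beta / shifted.se
    shifted = replace(shifted, pval=float(np.clip(2 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0)))
    records = list(study.outcome_table.records)
    records[index] = shifted
    new_alpha = study.alpha.copy()
    new_alpha[index] += multiplier * rec.se
    outliers = sorted(set(study.outlier_indices) | ({index} if multiplier != 0 else set()))
    return SimulatedStudy(
        exposure_tables=study.exposure_tables,
        outcome_table=study.outcome_table.with_records(records),
        ld=study.ld,
        theta=study.theta,
        gamma=study.gamma,
        alpha=new_alpha,
        outlier_indices=outliers,
    )


#: panel of instrument-set sizes mimicking a six-exposure fatty-acid study
DEMO_PANEL_SIZES = {"AA": 31, "LA": 54, "DHA": 6, "EPA": 4, "DPA": 3, "ALA": 1}


def demo_panel(seed: int = 0, scale: float = 1.0, theta: float = 0.03) -> dict[str, SimulatedStudy]:
    """Six simulated exposures with the panel's instrument-set sizes.

    The first exposure carries a true effect ``theta``; the rest are null.
    Each exposure gets its own independent study against a shared outcome
    design (sample sizes at the default scale).
    """
    out: dict[str, SimulatedStudy] = {}
    for i, (label, k) in enumerate(DEMO_PANEL_SIZES.items()):
        cfg = SimulationConfig(
            k_snps=k,
            theta=theta if i == 0 else 0.0,
            seed=seed + i,
            scale=scale,
        )
        study = simulate_study(cfg)
        for t in study.exposure_tables:
            t.trait_label = label
        out[label] = study
    return out
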