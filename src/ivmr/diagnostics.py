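"""Instrument-strength metrics and sensitivity analyses.

Covers the standard MR diagnostic battery: per-SNP variance explained and
F-statistics, Cochran's Q heterogeneity with I-squared bands, the Egger
intercept pleiotropy test, MR-PRESSO global/outlier/distortion tests,
leave-one-out analysis, funnel-plot data, conditional F-statistics for
multivariable MR, binary-outcome power, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .estimators import _ivw_point, egger, ivw, ratio_estimates
from .types import (
    HarmonizedSet,
    HeterogeneityResult,
    MREstimate,
    MVMRSet,
    PowerParams,
    PressoResult,
    StrengthResult,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Instrument strength
# ---------------------------------------------------------------------------

def snp_strength(hset: HarmonizedSet, n: int | None = None) -> StrengthResult:
    """Variance explained (R^2) and F-statistic per instrument.

    R^2 = 2 EAF (1-EAF) beta^2 / (2 EAF (1-EAF) beta^2 + 2 EAF (1-EAF) N se^2)
    and F = R^2 (N-2) / (1-R^2). A mean F above 10 is the conventional bar
    against weak-instrument bias. SNPs without EAF or N are excluded and
    listed in ``excluded``.
    """
    snp_ids, r2s, fs, excluded = [], [], [], []
    for rec in hset.records:
        n_j = rec.n_x if rec.n_x is not None else n
        if rec.eaf_x is None or n_j is None:
            excluded.append(rec.snp_id)
            continue
        het = 2.0 * rec.eaf_x * (1.0 - rec.eaf_x)
        num = het * rec.beta_x**2
        r2 = num / (num + het * n_j * rec.se_x**2)
        snp_ids.append(rec.snp_id)
        r2s.append(r2)
        fs.append(r2 * (n_j - 2) / (1.0 - r2))
    if excluded:
        logger.warning("snp_strength: excluded %s (missing eaf or n)", excluded)
    r2_arr, f_arr = np.asarray(r2s), np.asarray(fs)
    return StrengthResult(
        snp_ids=snp_ids,
        per_snp_r2=r2_arr,
        per_snp_f=f_arr,
        total_r2=float(r2_arr.sum()) if len(r2_arr) else math.nan,
        mean_f=float(f_arr.mean()) if len(f_arr) else math.nan,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Heterogeneity and pleiotropy
# ---------------------------------------------------------------------------

def cochran_q(hset: HarmonizedSet, beta_hat: float | None = None) -> HeterogeneityResult:
    """Cochran's Q of outcome betas around the fitted causal line.

    Q = sum (beta_y - beta_hat beta_x)^2 / se_y^2 on k-1 degrees of freedom;
    I^2 = max(0, (Q - df)/Q). ``beta_hat`` defaults to the fixed-effects IVW
    estimate.
    """
    if hset.n_snps < 2:
        raise ValueError("cochran_q requires at least 2 SNPs")
    bx, by, sy = hset.beta_x, hset.beta_y, hset.se_y
    if beta_hat is None:
        beta_hat, _ = _ivw_point(bx, by, sy)
    Q = float(np.sum((by - beta_hat * bx) ** 2 / sy**2))
    df = hset.n_snps - 1
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return HeterogeneityResult(Q=Q, df=df, pval=float(stats.chi2.sf(Q, df)), i2=i2)


def pleiotropy_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """Egger-intercept test for average directional pleiotropy.

    Returns (intercept, se, pval) — numerically identical to the intercept
    fields of :func:`ivmr.estimators.egger`.
    """
    res = egger(hset, compute_i2gx=False)
    return res.intercept, res.intercept_se, res.intercept_pval


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_ivw_betas(bx, by, sy) -> np.ndarray:
    """Leave-one-out IVW point estimates, vectorized."""
    w = 1.0 / sy**2
    sxx = np.sum(w * bx * bx)
    sxy = np.sum(w * bx * by)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    hset: HarmonizedSet,
    nsim: int = 1000,
    seed=None,
    outlier_alpha: float = 0.05,
    distortion_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: residual-sum-of-squares pleiotropy global test with
    per-SNP outlier and distortion tests.

    The observed RSS uses leave-one-out IVW predictions so each SNP's
    residual is independent of its own contribution. The null distribution
    comes from ``nsim`` parametric simulations redrawing both exposure and
    outcome betas. Outliers are flagged at Bonferroni ``outlier_alpha``/k on
    per-SNP simulation p-values; the distortion test compares the shift in
    the IVW estimate after outlier removal against random removals of the
    same number of SNPs.
    """
    k = hset.n_snps
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 SNPs")
    if nsim < 100:
        raise ValueError("nsim must be >= 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    bx, sx = hset.beta_x, hset.se_x
    by, sy = hset.beta_y, hset.se_y
    w = 1.0 / sy**2

    loo = _loo_ivw_betas(bx, by, sy)
    obs_terms = w * (by - loo * bx) ** 2
    obs_rss = float(obs_terms.sum())

    # parametric null: redraw betas about the leave-one-out fitted line
    bx_sim = rng.normal(bx, sx, size=(nsim, k))
    by_sim = rng.normal(loo * bx, sy, size=(nsim, k))
    w_row = w[None, :]
    sxx = np.sum(w_row * bx_sim**2, axis=1, keepdims=True)
    sxy = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True)
    loo_sim = (sxy - w_row * bx_sim * by_sim) / (sxx - w_row * bx_sim**2)
    sim_terms = w_row * (by_sim - loo_sim * bx_sim) ** 2
    sim_rss = sim_terms.sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (nsim + 1))
    outlier_pvals = (1 + np.sum(sim_terms >= obs_terms[None, :], axis=0)) / (nsim + 1)
    threshold = outlier_alpha / k
    outliers = [int(i) for i in np.where(outlier_pvals < threshold)[0]]

    raw, _ = ivw(hset)
    adjusted = None
    distortion_p = None
    if outliers:
        keep = [i for i in range(k) if i not in outliers]
        if len(keep) >= 1:
            adj_set = hset.subset(keep)
            adjusted, _ = ivw(adj_set)
            # distortion: observed shift vs shifts from random removals
            n_out = len(outliers)
            shifts = np.empty(min(nsim, 1000))
            for s in range(len(shifts)):
                drop = rng.choice(k, size=n_out, replace=False)
                mask = np.ones(k, dtype=bool)
                mask[drop] = False
                b_rand, _ = _ivw_point(bx[mask], by[mask], sy[mask])
                shifts[s] = b_rand - raw.beta
            obs_shift = adjusted.beta - raw.beta
            distortion_p = float(
                (1 + np.sum(np.abs(shifts) >= abs(obs_shift))) / (len(shifts) + 1)
            )

    return PressoResult(
        global_rss=obs_rss,
        global_p=global_p,
        outlier_pvals=np.asarray(outlier_pvals),
        outliers=outliers,
        outlier_snp_ids=[hset.snp_ids[i] for i in outliers],
        distortion_p=distortion_p,
        raw_estimate=raw,
        adjusted_estimate=adjusted,
    )


# ---------------------------------------------------------------------------
# Leave-one-out and funnel data
# ---------------------------------------------------------------------------

def leave_one_out(hset: HarmonizedSet) -> list[MREstimate]:
    """IVW recomputed k times, omitting one SNP each time."""
    if hset.n_snps < 2:
        raise ValueError("leave-one-out requires at least 2 SNPs")
    out = []
    for i in range(hset.n_snps):
        sub = hset.subset([j for j in range(hset.n_snps) if j != i])
        est, _ = ivw(sub)
        est.exposure = hset.exposure_label
        out.append(est)
    return out


def funnel_data(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-SNP (ratio, precision = 1/se_ratio) pairs for funnel plots."""
    if hset.n_snps == 0:
        raise ValueError("funnel_data requires at least 1 SNP")
    ratio, se_ratio, excluded = ratio_estimates(hset)
    return ratio, 1.0 / se_ratio, excluded


# ---------------------------------------------------------------------------
# Conditional F (MVMR instrument strength)
# ---------------------------------------------------------------------------

def conditional_f(mset: MVMRSet) -> dict[str, float]:
    """Conditional F-statistic per exposure in a multivariable MR set.

    For exposure k, its instrument betas are regressed on the other
    exposures' betas (WLS through the origin with weights 1/se_xk^2); the
    weighted residual Q-statistic divided by L - (K-1) - 1 measures the
    strength of the instruments for exposure k conditional on the others.
    Cross-exposure sampling covariance is taken as zero (non-overlapping
    exposure samples).
    """
    L, K = mset.n_snps, mset.n_exposures
    if L <= K:
        raise ValueError("conditional F needs more SNPs than exposures")
    out: dict[str, float] = {}
    for k, label in enumerate(mset.exposure_labels):
        yk = mset.beta_x[:, k]
        X = np.delete(mset.beta_x, k, axis=1)
        w = 1.0 / mset.se_x[:, k] ** 2
        WX = X * w[:, None]
        coef = np.linalg.lstsq(WX.T @ X, WX.T @ yk, rcond=None)[0]
        resid = yk - X @ coef
        Q = float(np.sum(w * resid**2))
        out[label] = Q / (L - (K - 1) - 1)
    return out


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def power_binary(p: PowerParams) -> float:
    """Power of a two-sample MR Wald test with a binary outcome.

    Uses the standard non-centrality approximation: with case fraction
    K = cases/(cases+controls) and assumed causal odds ratio OR per SD,
    b = K (OR / (1 + K (OR - 1)) - 1), NCP = N R^2 b^2 / (K(1-K) - b^2),
    and power is the upper tail of a noncentral chi-square(1, NCP) at the
    central 1-alpha critical value.
    """
    if p.r2 == 0:
        return p.alpha
    n = p.n_cases + p.n_controls
    K = p.n_cases / n
    b = K * (p.true_or / (1.0 + K * (p.true_or - 1.0)) - 1.0)
    denom = K * (1.0 - K) - b**2
    ncp = n * p.r2 * b**2 / denom
    crit = stats.chi2.ppf(1.0 - p.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp))


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
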