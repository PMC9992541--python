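"""Causal-effect estimators for two-sample summary-data MR.

All estimators consume a :class:`~ivmr.types.HarmonizedSet` (or
:class:`~ivmr.types.MVMRSet`) and return :class:`~ivmr.types.MREstimate`
objects on the log-odds scale. The suite covers:

* inverse-variance weighted (IVW), fixed or multiplicative random effects,
  with the fixed/random choice automated by the I-squared rule;
* MR-Egger regression (slope + pleiotropy intercept), with the I2_GX
  regression-dilution metric and SIMEX measurement-error correction;
* weighted median and weighted mode (parametric-bootstrap SEs);
* debiased IVW, robust to many weak instruments;
* multivariable (MVMR) IVW.

Weighted least squares is solved in closed form: IVW is regression of
outcome betas on exposure betas through the origin with weights 1/se_y^2,
Egger adds an intercept, MVMR generalises the design matrix to K exposures.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats

from .types import (
    EggerResult,
    HarmonizedSet,
    HeterogeneityResult,
    MREstimate,
    MVMRSet,
)

logger = logging.getLogger(__name__)

_MIN_BOOTSTRAP = 100


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Per-variant ratio estimates
# ---------------------------------------------------------------------------

def ratio_estimates(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-SNP Wald ratios beta_y/beta_x with first-order delta-method SEs.

    SNPs with beta_x exactly 0 have no ratio; they are excluded and their
    ids returned as the third element.
    """
    bx, by, sy = hset.beta_x, hset.beta_y, hset.se_y
    usable = bx != 0
    excluded = [sid for sid, u in zip(hset.snp_ids, usable) if not u]
    if excluded:
        logger.warning("ratio estimates: excluded %s (beta_x = 0)", excluded)
    ratio = by[usable] / bx[usable]
    se_ratio = sy[usable] / np.abs(bx[usable])
    return ratio, se_ratio, excluded


# ---------------------------------------------------------------------------
# IVW (and the Wald-ratio degenerate case)
# ---------------------------------------------------------------------------

def _ivw_point(bx, by, sy) -> tuple[float, float]:
    """Closed-form IVW beta and fixed-effects SE."""
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    sxy = float(np.sum(w * bx * by))
    return sxy / sxx, sxx ** -0.5


def wald_ratio(hset: HarmonizedSet) -> MREstimate:
    """Single-instrument causal estimate beta_y/beta_x."""
    if hset.n_snps != 1:
        raise ValueError("wald_ratio requires exactly one SNP")
    r, s, excluded = ratio_estimates(hset)
    if excluded:
        raise ValueError("cannot form Wald ratio: beta_x = 0")
    return MREstimate.from_wald(
        "wald_ratio", float(r[0]), float(s[0]), 1,
        exposure=hset.exposure_label, outcome=hset.outcome_label,
    )


def ivw(
    hset: HarmonizedSet, effects_rule: str = "auto"
) -> tuple[MREstimate, HeterogeneityResult | None]:
    """Inverse-variance weighted causal estimate.

    ``effects_rule`` selects the error model: ``fixed``, ``random``
    (multiplicative random effects, SE inflated by max(1, sqrt(Q/(k-1)))),
    or ``auto`` — random effects when between-instrument heterogeneity is
    at least moderate (I-squared >= 50%), fixed otherwise.

    A single instrument degenerates to the Wald ratio (no heterogeneity
    statistic is defined in that case).
    """
    if hset.n_snps == 0:
        raise ValueError("ivw requires at least one kept SNP")
    if hset.n_snps == 1:
        return wald_ratio(hset), None
    if effects_rule not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown effects_rule {effects_rule!r}")

    bx, by, sy = hset.beta_x, hset.beta_y, hset.se_y
    beta, se_fixed = _ivw_point(bx, by, sy)
    k = hset.n_snps
    Q = float(np.sum((by - beta * bx) ** 2 / sy**2))
    df = k - 1
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    het = HeterogeneityResult(Q=Q, df=df, pval=float(stats.chi2.sf(Q, df)), i2=i2)

    use_random = effects_rule == "random" or (effects_rule == "auto" and i2 >= 0.5)
    inflation = max(1.0, math.sqrt(Q / df)) if use_random else 1.0
    method = "ivw_random" if use_random else "ivw_fixed"
    est = MREstimate.from_wald(
        method, beta, se_fixed * inflation, k,
        exposure=hset.exposure_label, outcome=hset.outcome_label,
    )
    return est, het


# ---------------------------------------------------------------------------
# MR-Egger, I2_GX and SIMEX
# ---------------------------------------------------------------------------

def _orient(bx, by):
    """Egger sign convention: flip variants so every exposure effect is >= 0."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def _egger_fit(bx, by, sy) -> tuple[float, float, float, float]:
    """Weighted least squares of by on bx with intercept, weights 1/sy^2.

    Returns (slope, slope_se, intercept, intercept_se); SEs use the
    analytic WLS covariance (no dispersion scaling beyond max(1, sigma)).
    """
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    k = len(bx)
    # multiplicative overdispersion, floored at 1 (standard Egger practice)
    sigma2 = max(1.0, float(np.sum(w * resid**2) / (k - 2))) if k > 2 else 1.0
    cov = np.linalg.inv(xtwx) * sigma2
    return float(coef[1]), float(math.sqrt(cov[1, 1])), float(coef[0]), float(math.sqrt(cov[0, 0]))


def egger(hset: HarmonizedSet, compute_i2gx: bool = True) -> EggerResult:
    """MR-Egger regression.

    The slope estimates the causal effect under the InSIDE assumption; the
    intercept estimates average directional pleiotropy and its test doubles
    as the pleiotropy test. Inference is t-based on k-2 degrees of freedom.
    """
    if hset.n_snps < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    bx, by = _orient(hset.beta_x, hset.beta_y)
    slope, slope_se, intercept, int_se = _egger_fit(bx, by, hset.se_y)
    k = hset.n_snps
    slope_est = MREstimate.from_wald(
        "egger_slope", slope, slope_se, k, df=k - 2,
        exposure=hset.exposure_label, outcome=hset.outcome_label,
    )
    int_p = 2.0 * stats.t.sf(abs(intercept) / int_se, k - 2) if int_se > 0 else 1.0
    return EggerResult(
        slope=slope_est,
        intercept=intercept,
        intercept_se=int_se,
        intercept_pval=float(int_p),
        i2_gx=i2_gx(hset) if compute_i2gx else None,
    )


def i2_gx(hset: HarmonizedSet) -> float:
    """I2 statistic for exposure-effect measurement error (NOME violation).

    Cochran's Q of the (oriented) exposure betas around their
    inverse-variance-weighted mean, with variances se_x^2. Values below 0.9
    signal regression dilution of the Egger slope, conventionally corrected
    with SIMEX.
    """
    if hset.n_snps < 2:
        raise ValueError("i2_gx requires at least 2 SNPs")
    bx = np.abs(hset.beta_x)
    sx = hset.se_x
    w = 1.0 / sx**2
    mu = float(np.sum(w * bx) / np.sum(w))
    Q = float(np.sum(w * (bx - mu) ** 2))
    if Q <= 0:
        return 0.0
    return max(0.0, (Q - (hset.n_snps - 1)) / Q)


def simex_egger(
    hset: HarmonizedSet,
    lambdas: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0),
    B: int = 200,
    seed=None,
) -> EggerResult:
    """Simulation-extrapolation correction of the Egger slope.

    Measurement error in the exposure betas attenuates the Egger slope. SIMEX
    adds extra noise with variance lambda * se_x^2 for each lambda in the
    grid, averages the refitted slope over B replicates, fits a quadratic in
    lambda, and extrapolates to lambda = -1 (zero measurement error). The SE
    comes from a jackknife over replicates.
    """
    if hset.n_snps < 3:
        raise ValueError("SIMEX-Egger requires at least 3 SNPs")
    if B < _MIN_BOOTSTRAP:
        raise ValueError(f"B must be >= {_MIN_BOOTSTRAP}")
    rng = _rng(seed)
    bx, by = _orient(hset.beta_x, hset.beta_y)
    sx, sy = hset.se_x, hset.se_y
    k = hset.n_snps

    lambdas = np.asarray(lambdas, dtype=float)
    slopes = np.empty((len(lambdas), B))
    intercepts = np.empty((len(lambdas), B))
    dropped = 0
    for li, lam in enumerate(lambdas):
        for b in range(B):
            if lam == 0:
                bxp = bx
            else:
                bxp = bx + rng.normal(0.0, math.sqrt(lam) * sx)
            try:
                s, _, c, _ = _egger_fit(bxp, by, sy)
            except np.linalg.LinAlgError:
                s, c = np.nan, np.nan
            slopes[li, b], intercepts[li, b] = s, c
    bad = ~np.isfinite(slopes)
    dropped = int(bad.sum())
    if dropped:
        logger.warning("SIMEX: %d non-finite replicates dropped", dropped)

    def extrapolate(values: np.ndarray) -> float:
        means = np.nanmean(values, axis=1)
        coef = np.polynomial.polynomial.polyfit(lambdas, means, 2)
        return float(coef[0] - coef[1] + coef[2])  # evaluate at lambda = -1

    slope_hat = extrapolate(slopes)
    intercept_hat = extrapolate(intercepts)

    # jackknife over replicates
    jack = np.empty(B)
    for b in range(B):
        mask = np.ones(B, dtype=bool)
        mask[b] = False
        jack[b] = extrapolate(slopes[:, mask])
    jbar = jack.mean()
    slope_se = math.sqrt(max((B - 1) / B * float(np.sum((jack - jbar) ** 2)), 0.0))
    if slope_se == 0.0:
        # no perturbation randomness (e.g. all se_x = 0): fall back to the
        # naive Egger slope SE
        slope_se = _egger_fit(bx, by, sy)[1]

    jack_i = np.empty(B)
    for b in range(B):
        mask = np.ones(B, dtype=bool)
        mask[b] = False
        jack_i[b] = extrapolate(intercepts[:, mask])
    ibar = jack_i.mean()
    int_se = math.sqrt(max((B - 1) / B * float(np.sum((jack_i - ibar) ** 2)), 0.0))
    if int_se == 0.0:
        int_se = _egger_fit(bx, by, sy)[3]

    slope_est = MREstimate.from_wald(
        "egger_simex", slope_hat, slope_se, k, df=k - 2,
        exposure=hset.exposure_label, outcome=hset.outcome_label,
    )
    int_p = 2.0 * stats.t.sf(abs(intercept_hat) / int_se, k - 2) if int_se > 0 else 1.0
    return EggerResult(
        slope=slope_est,
        intercept=intercept_hat,
        intercept_se=int_se,
        intercept_pval=float(int_p),
        i2_gx=i2_gx(hset),
        simex_applied=True,
    )


# ---------------------------------------------------------------------------
# Weighted median / weighted mode
# ---------------------------------------------------------------------------

def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio)
    r = ratio[order]
    w = weight[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _bootstrap_se(point_fn, hset: HarmonizedSet, B: int, rng) -> float:
    """Parametric bootstrap: redraw betas from their sampling distributions."""
    bx, sx = hset.beta_x, hset.se_x
    by, sy = hset.beta_y, hset.se_y
    vals = np.empty(B)
    for b in range(B):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ok = bxs != 0
        vals[b] = point_fn(bys[ok] / bxs[ok], (sy[ok] / np.abs(bxs[ok])) ** -2)
    return float(np.std(vals, ddof=1))


def weighted_median(hset: HarmonizedSet, B: int = 1000, seed=None) -> MREstimate:
    """Weighted median of per-SNP ratio estimates.

    Consistent when instruments carrying at least half the total weight are
    valid. Weights are inverse-variance (1/se_ratio^2); the estimate
    interpolates the ratio order statistics at standardized cumulative
    weight 0.5. SE by parametric bootstrap.
    """
    if hset.n_snps < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    if B < _MIN_BOOTSTRAP:
        logger.warning("weighted_median: B=%d is small; SE will be noisy", B)
    rng = _rng(seed)
    ratio, se_ratio, _ = ratio_estimates(hset)
    est = _weighted_median_point(ratio, se_ratio**-2)
    se = _bootstrap_se(_weighted_median_point, hset, B, rng)
    return MREstimate.from_wald(
        "weighted_median", est, se, hset.n_snps,
        exposure=hset.exposure_label, outcome=hset.outcome_label,
    )


def _mode_bandwidth(ratio: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: 0.9 min(sd, MAD) k^(-1/5), scaled by phi."""
    sd = float(np.std(ratio, ddof=1)) if len(ratio) > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratio, scale="normal"))
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    return phi * 0.9 * spread * len(ratio) ** (-1 / 5)


def _weighted_mode_point(ratio: np.ndarray, weight: np.ndarray, phi: float = 1.0) -> float:
    h = _mode_bandwidth(ratio, phi)
    if h == 0.0 or np.ptp(ratio) == 0.0:
        # degenerate density: all mass on one support point
        return float(ratio[np.argmax(weight)]) if np.ptp(ratio) else float(ratio[0])
    w = weight / np.sum(weight)
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 512)
    dens = (w[None, :] * stats.norm.pdf(grid[:, None], loc=ratio[None, :], scale=h)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(
    hset: HarmonizedSet, phi: float = 1.0, B: int = 1000, seed=None
) -> MREstimate:
    """Weighted mode of per-SNP ratio estimates.

    Consistent when the largest cluster of similar ratios comes from valid
    instruments (ZEMPA). The estimate is the argmax of a weighted
    normal-kernel density over the ratios with bandwidth phi times the
    modified-MAD rule of thumb. SE by parametric bootstrap.
    """
    if hset.n_snps < 3:
        raise ValueError("weighted mode requires at least 3 SNPs")
    rng = _rng(seed)
    ratio, se_ratio, _ = ratio_estimates(hset)
    est = _weighted_mode_point(ratio, se_ratio**-2, phi)
    se = _bootstrap_se(lambda r, w: _weighted_mode_point(r, w, phi), hset, B, rng)
    return MREstimate.from_wald(
        "weighted_mode", est, se, hset.n_snps,
        exposure=hset.exposure_label, outcome=hset.outcome_label,
    )


# ---------------------------------------------------------------------------
# Debiased IVW
# ---------------------------------------------------------------------------

def debiased_ivw(hset: HarmonizedSet) -> MREstimate:
    """Weak-instrument-robust IVW.

    Classical IVW is attenuated when exposure effects are estimated with
    error; subtracting each se_x^2 from the squared exposure beta in the
    denominator removes the first-order bias, which matters for instrument
    sets admitted at relaxed significance thresholds. The variance is the
    no-overdispersion sandwich form.
    """
    if hset.n_snps < 1:
        raise ValueError("debiased IVW requires at least 1 SNP")
    if hset.n_snps < 2:
        logger.warning("debiased IVW on a single SNP: variance is first-order only")
    bx, sx = hset.beta_x, hset.se_x
    by, sy = hset.beta_y, hset.se_y
    v = 1.0 / sy**2
    num = float(np.sum(v * bx * by))
    den = float(np.sum(v * (bx**2 - sx**2)))
    if den <= 0:
        raise ValueError(
            "debiased IVW denominator is non-positive: instruments are too "
            "weak in aggregate (sum of beta_x^2 does not exceed sum of se_x^2)"
        )
    beta = num / den
    var = float(
        np.sum(v**2 * (bx**2 * sy**2 + beta**2 * sx**2 * (bx**2 + sx**2)))
    ) / den**2
    return MREstimate.from_wald(
        "debiased_ivw", beta, math.sqrt(var), hset.n_snps,
        exposure=hset.exposure_label, outcome=hset.outcome_label,
    )


# ---------------------------------------------------------------------------
# Multivariable MR
# ---------------------------------------------------------------------------

def mvmr_ivw(mset: MVMRSet) -> list[MREstimate]:
    """Multivariable IVW: joint WLS of outcome betas on the exposure matrix.

    No intercept; weights 1/se_y^2. Each exposure's coefficient is its
    direct effect on the outcome conditional on the other exposures.
    """
    X = mset.beta_x
    y = mset.beta_y
    w = 1.0 / mset.se_y**2
    WX = X * w[:, None]
    xtwx = X.T @ WX
    if np.linalg.matrix_rank(xtwx) < X.shape[1]:
        raise ValueError(
            f"rank-deficient exposure matrix: collinear exposures among "
            f"{mset.exposure_labels}"
        )
    coef = np.linalg.solve(xtwx, WX.T @ y)
    cov = np.linalg.inv(xtwx)
    out = []
    for k, label in enumerate(mset.exposure_labels):
        out.append(
            MREstimate.from_wald(
                "mvmr_ivw", float(coef[k]), float(math.sqrt(cov[k, k])),
                mset.n_snps, exposure=label,
            )
        )
    return out
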