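import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from ivmr.estimators import (
    debiased_ivw,
    egger,
    i2_gx,
    ivw,
    mvmr_ivw,
    ratio_estimates,
    simex_egger,
    weighted_median,
    weighted_mode,
)
from ivmr.harmonize import harmonize
from ivmr.simulate import SimulationConfig, simulate_study
from ivmr.types import MVMRSet

from conftest import make_hset


# ---------------------------------------------------------------------------
# Ratio estimates
# ---------------------------------------------------------------------------

def test_ratio_arithmetic():
    hset = make_hset([0.2, 0.5, 0.1], [0.01] * 3, [0.01, 0.0, 0.02], [0.01, 0.02, 0.01])
    ratio, se_ratio, excluded = ratio_estimates(hset)
    assert ratio[0] == pytest.approx(0.05)
    assert ratio[1] == 0.0
    assert se_ratio[1] == pytest.approx(0.04)
    assert excluded == []


def test_ratio_zero_beta_x_excluded():
    hset = make_hset([0.2, 0.0], [0.01] * 2, [0.01, 0.01], [0.01] * 2)
    ratio, _, excluded = ratio_estimates(hset)
    assert len(ratio) == 1 and excluded == ["rs2"]


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def test_ivw_homogeneous_pair():
    hset = make_hset([1, 1], [0.01] * 2, [0.5, 0.5], [0.1] * 2)
    est, het = ivw(hset)
    assert est.beta == pytest.approx(0.5)
    assert het.Q == pytest.approx(0.0, abs=1e-20)
    assert est.method == "ivw_fixed"


def test_ivw_matches_normal_equations():
    hset = make_hset([0.2, 0.4, 0.3], [0.01] * 3, [0.01, 0.03, 0.02], [0.01] * 3)
    est, _ = ivw(hset)
    assert est.beta == pytest.approx(0.02 / 0.29, rel=1e-12)


def test_ivw_single_snp_degenerates_to_wald_ratio():
    hset = make_hset([0.2], [0.01], [0.01], [0.01])
    est, het = ivw(hset)
    assert est.method == "wald_ratio" and het is None
    assert est.beta == pytest.approx(0.05)
    assert est.se == pytest.approx(0.05)


def test_ivw_equals_statsmodels_wls_through_origin(rng):
    """Independent oracle: WLS of beta_y on beta_x, no intercept, w=1/se_y^2."""
    for _ in range(10):
        k = rng.integers(3, 20)
        bx = rng.normal(0.2, 0.1, k)
        by = rng.normal(0.0, 0.05, k)
        sy = rng.uniform(0.01, 0.1, k)
        hset = make_hset(bx, np.full(k, 0.01), by, sy)
        est, _ = ivw(hset, effects_rule="fixed")
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)


def test_random_effects_se_never_below_fixed():
    hset = make_hset([0.2, 0.4, 0.3], [0.01] * 3, [0.05, -0.02, 0.04], [0.01] * 3)
    fixed, het = ivw(hset, effects_rule="fixed")
    random, _ = ivw(hset, effects_rule="random")
    assert random.se >= fixed.se
    assert random.beta == pytest.approx(fixed.beta)
    # homogeneous data: Q <= k-1 so the two coincide
    hom = make_hset([1, 1, 1], [0.01] * 3, [0.5, 0.5, 0.5], [0.1] * 3)
    f, _ = ivw(hom, effects_rule="fixed")
    r, _ = ivw(hom, effects_rule="random")
    assert r.se == pytest.approx(f.se)


def test_auto_rule_switches_on_i2():
    heterogeneous = make_hset([0.2, 0.4, 0.3], [0.01] * 3, [0.09, -0.05, 0.06], [0.01] * 3)
    est, het = ivw(heterogeneous, effects_rule="auto")
    assert het.i2 >= 0.5 and est.method == "ivw_random"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_ivw_invariant_to_snp_order(seed):
    rng = np.random.default_rng(seed)
    k = 8
    bx, by = rng.normal(0.2, 0.05, k), rng.normal(0.01, 0.02, k)
    sy = rng.uniform(0.005, 0.05, k)
    hset = make_hset(bx, np.full(k, 0.01), by, sy)
    perm = rng.permutation(k)
    shuffled = make_hset(bx[perm], np.full(k, 0.01), by[perm], sy[perm])
    a, _ = ivw(hset)
    b, _ = ivw(shuffled)
    assert a.beta == pytest.approx(b.beta, abs=1e-12)
    assert a.se == pytest.approx(b.se, abs=1e-12)


# ---------------------------------------------------------------------------
# Egger
# ---------------------------------------------------------------------------

def test_egger_exact_on_collinear_points():
    hset = make_hset([1, 2, 3], [0.01] * 3, [0.51, 1.01, 1.51], [0.1] * 3)
    res = egger(hset, compute_i2gx=False)
    assert res.slope.beta == pytest.approx(0.5, abs=1e-12)
    assert res.intercept == pytest.approx(0.01, abs=1e-12)


def test_egger_matches_statsmodels_wls(rng):
    k = 10
    bx = rng.normal(0.3, 0.1, k)
    by = 0.1 * bx + rng.normal(0.01, 0.02, k)
    sy = rng.uniform(0.01, 0.05, k)
    hset = make_hset(np.abs(bx), np.full(k, 0.01), by, sy)
    res = egger(hset, compute_i2gx=False)
    X = sm.add_constant(np.abs(bx))
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    assert res.slope.beta == pytest.approx(fit.params[1], abs=1e-10)
    assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)


def test_egger_orientation_invariance():
    """Flipping a SNP's alleles (sign of both betas) leaves Egger unchanged."""
    bx = np.array([0.2, -0.4, 0.3, 0.25])
    by = np.array([0.02, -0.03, 0.01, 0.04])
    base = egger(make_hset(bx, [0.01] * 4, by, [0.01] * 4), compute_i2gx=False)
    flipped = egger(make_hset(-bx, [0.01] * 4, -by, [0.01] * 4), compute_i2gx=False)
    assert base.slope.beta == pytest.approx(flipped.slope.beta, abs=1e-12)
    assert base.intercept == pytest.approx(flipped.intercept, abs=1e-12)


def test_egger_requires_three_snps():
    with pytest.raises(ValueError):
        egger(make_hset([0.2, 0.3], [0.01] * 2, [0.01, 0.02], [0.01] * 2))


def test_egger_intercept_p_uniform_under_balanced_pleiotropy():
    """With zero-mean pleiotropy, the intercept test rejects at ~nominal rate."""
    rejections = 0
    reps = 400
    for r in range(reps):
        study = simulate_study(
            SimulationConfig(k_snps=20, theta=0.03, pleiotropy_mean=0.0,
                             pleiotropy_sd=0.01, seed=70_000 + r)
        )
        hset = harmonize(study.exposure_table, study.outcome_table)
        res = egger(hset, compute_i2gx=False)
        rejections += res.intercept_pval < 0.05
    rate = rejections / reps
    mc_se = np.sqrt(0.05 * 0.95 / reps)
    assert rate <= 0.05 + 3 * mc_se


# ---------------------------------------------------------------------------
# I2_GX and SIMEX
# ---------------------------------------------------------------------------

def test_i2gx_limits():
    tiny_se = make_hset([0.1, 0.2, 0.3], [1e-6] * 3, [0.01] * 3, [0.01] * 3)
    assert i2_gx(tiny_se) > 0.999
    identical = make_hset([0.2, 0.2, 0.2], [0.05] * 3, [0.01] * 3, [0.01] * 3)
    assert i2_gx(identical) == 0.0


def test_simex_reduces_to_naive_without_measurement_error():
    hset = make_hset([0.1, 0.2, 0.3, 0.4], [1e-12] * 4,
                     [0.012, 0.021, 0.032, 0.04], [0.01] * 4)
    naive = egger(hset, compute_i2gx=False)
    sim = simex_egger(hset, B=100, seed=1)
    assert sim.slope.beta == pytest.approx(naive.slope.beta, abs=1e-9)
    assert sim.simex_applied


def test_simex_moves_attenuated_slope_toward_truth():
    """Weak exposure betas dilute the Egger slope; SIMEX corrects on average."""
    theta = 0.2
    naive_vals, simex_vals = [], []
    for r in range(30):
        study = simulate_study(
            SimulationConfig(k_snps=30, theta=theta, gamma_mean=0.15,
                             gamma_sd=0.1, n_exposure=400, seed=100 + r)
        )
        hset = harmonize(study.exposure_table, study.outcome_table)
        naive_vals.append(egger(hset, compute_i2gx=False).slope.beta)
        simex_vals.append(simex_egger(hset, B=100, seed=r).slope.beta)
    naive_bias = abs(np.mean(naive_vals) - theta)
    simex_bias = abs(np.mean(simex_vals) - theta)
    assert simex_bias < naive_bias


# ---------------------------------------------------------------------------
# Weighted median / mode
# ---------------------------------------------------------------------------

def test_weighted_median_symmetric_equal_weights():
    hset = make_hset([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.3], [0.1] * 3)
    est = weighted_median(hset, B=200, seed=0)
    assert est.beta == pytest.approx(0.2)


def test_weighted_median_interpolation_with_unequal_weights():
    """Ratios (1,2,3), weights (1,1,2): interpolate at s=0.5 -> 2.333."""
    hset = make_hset([1, 1, 1], [0.01] * 3, [1, 2, 3], [1, 1, 1 / np.sqrt(2)])
    est = weighted_median(hset, B=200, seed=0)
    assert est.beta == pytest.approx(7 / 3, abs=1e-9)


def test_weighted_median_within_ratio_range(rng):
    for _ in range(20):
        k = int(rng.integers(3, 12))
        bx = rng.uniform(0.1, 0.5, k)
        by = rng.normal(0.02, 0.05, k)
        sy = rng.uniform(0.01, 0.1, k)
        hset = make_hset(bx, np.full(k, 0.01), by, sy)
        est = weighted_median(hset, B=100, seed=1)
        ratios = by / bx
        assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12


def test_weighted_mode_majority_cluster():
    hset = make_hset([1, 1, 1, 1], [0.01] * 4, [0.5, 0.5, 0.5, 0.9], [0.1] * 4)
    for phi in (0.25, 0.5, 1.0):
        est = weighted_mode(hset, phi=phi, B=100, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.02)


def test_weighted_mode_degenerate_support():
    hset = make_hset([1, 1, 1], [0.01] * 3, [0.4, 0.4, 0.4], [0.1] * 3)
    est = weighted_mode(hset, B=100, seed=0)
    assert est.beta == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# Debiased IVW
# ---------------------------------------------------------------------------

def test_divw_equals_ivw_when_sex_zero():
    # se_x -> 0 limit (exact zero violates the kept-record invariant)
    hset = make_hset([0.2, 0.4, 0.3], [1e-15] * 3, [0.01, 0.03, 0.02], [0.01] * 3)
    est, _ = ivw(hset, effects_rule="fixed")
    div = debiased_ivw(hset)
    assert div.beta == pytest.approx(est.beta, abs=1e-14)
    assert div.se == pytest.approx(est.se, rel=1e-10)


def test_divw_single_snp_plug_in():
    hset = make_hset([0.2], [0.1], [0.01], [0.01])
    assert debiased_ivw(hset).beta == pytest.approx(20 / 300, abs=1e-12)


def test_divw_converges_to_ivw_as_sex_shrinks():
    bx, by = [0.2, 0.4, 0.3], [0.01, 0.03, 0.02]
    target, _ = ivw(make_hset(bx, [1e-15] * 3, by, [0.01] * 3), effects_rule="fixed")
    gaps = []
    for sx in (0.08, 0.04, 0.02, 0.01, 0.005):
        div = debiased_ivw(make_hset(bx, [sx] * 3, by, [0.01] * 3))
        gaps.append(abs(div.beta - target.beta))
    assert all(a > b for a, b in zip(gaps, gaps[1:]))


def test_divw_weak_aggregate_raises():
    hset = make_hset([0.01, 0.01], [0.5, 0.5], [0.01, 0.01], [0.01] * 2)
    with pytest.raises(ValueError, match="weak"):
        debiased_ivw(hset)


# ---------------------------------------------------------------------------
# MVMR
# ---------------------------------------------------------------------------

def _mvmr_from_arrays(bx, sx, by, sy):
    L, K = bx.shape
    return MVMRSet(
        exposure_labels=[f"exp{k}" for k in range(K)],
        snp_ids=[f"rs{i}" for i in range(L)],
        beta_x=bx, se_x=sx, beta_y=by, se_y=sy,
    )


def test_mvmr_reduces_to_univariable_when_second_exposure_null(rng):
    """A second exposure orthogonal to signal and outcome changes nothing."""
    L = 8
    bx1 = rng.normal(0.3, 0.05, L)
    by = 0.1 * bx1 + rng.normal(0, 0.01, L)
    sy = rng.uniform(0.01, 0.03, L)
    w = 1.0 / sy**2
    # second column W-orthogonal to both bx1 and by: normal equations decouple
    u1 = bx1
    u2 = by - u1 * np.dot(w * by, u1) / np.dot(w * u1, u1)
    v = rng.normal(0, 0.01, L)
    for u in (u1, u2):
        v = v - u * np.dot(w * v, u) / np.dot(w * u, u)
    bx = np.column_stack([bx1, v])
    mset = _mvmr_from_arrays(bx, np.full((L, 2), 0.01), by, sy)
    ests = mvmr_ivw(mset)
    uni, _ = ivw(make_hset(bx1, np.full(L, 0.01), by, sy), effects_rule="fixed")
    assert ests[0].beta == pytest.approx(uni.beta, abs=1e-10)


def test_mvmr_matches_linear_algebra_oracle(rng):
    L, K = 8, 2
    bx = rng.normal(0.3, 0.1, (L, K))
    by = bx @ np.array([0.1, -0.05]) + rng.normal(0, 0.01, L)
    sy = rng.uniform(0.01, 0.05, L)
    mset = _mvmr_from_arrays(bx, np.full((L, K), 0.01), by, sy)
    ests = mvmr_ivw(mset)
    # independent oracle: explicit weighted normal equations
    W = np.diag(1.0 / sy**2)
    coef = np.linalg.solve(bx.T @ W @ bx, bx.T @ W @ by)
    for k in range(K):
        assert ests[k].beta == pytest.approx(coef[k], abs=1e-10)


def test_mvmr_collinear_exposures_rejected(rng):
    L = 8
    col = rng.normal(0.3, 0.1, L)
    bx = np.column_stack([col, 2 * col])
    mset = _mvmr_from_arrays(bx, np.full((L, 2), 0.01),
                             rng.normal(0, 0.01, L), np.full(L, 0.02))
    with pytest.raises(ValueError, match="collinear|rank"):
        mvmr_ivw(mset)
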