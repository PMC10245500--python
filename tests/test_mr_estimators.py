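import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrpipe.harmonization import HarmonizedInstrument
from mrpipe.mr_estimators import (
    InsufficientInstrumentsError,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    ratio_estimates,
    rescale_estimate,
    wald_ratio,
    weighted_median,
)

from conftest import make_instruments


# --- Wald ratios and weights -------------------------------------------------

def test_ratio_and_weight_arithmetic():
    inst = make_instruments([0.1], [0.02], [0.01])
    ratios, weights, ids = ratio_estimates(inst)
    assert ratios[0] == pytest.approx(0.2)
    assert weights[0] == pytest.approx(100.0)


def test_zero_beta_x_excluded():
    inst = make_instruments([0.1, 0.0], [0.02, 0.01], [0.01, 0.01])
    ratios, _, ids = ratio_estimates(inst)
    assert len(ratios) == 1 and ids == ["rs1"]
    with pytest.raises(InsufficientInstrumentsError):
        ratio_estimates(make_instruments([0.0], [0.01], [0.01]))


def test_weights_match_delta_method_variance():
    """First-order weight equals 1/Var(ratio) when only beta_Y is noisy."""
    bx, by, sy = 0.08, 0.02, 0.013
    inst = make_instruments([bx], [by], [sy])
    _, w, _ = ratio_estimates(inst)
    var_ratio = sy**2 / bx**2  # delta method, leading term
    assert w[0] == pytest.approx(1.0 / var_ratio, rel=1e-12)


def test_wald_ratio_single_snp():
    h = make_instruments([0.1], [0.02], [0.01])[0]
    est = wald_ratio(h)
    assert est.beta == pytest.approx(0.2)
    assert est.se == pytest.approx(0.1)


# --- IVW ---------------------------------------------------------------------

def ivw_wls_oracle(bx, by, sy):
    """Independent check: weighted LS of by on bx through the origin,
    weights 1/sy^2, with multiplicative over-dispersion."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    w = 1.0 / sy**2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    resid = by - beta * bx
    q = np.sum(w * resid**2)
    n = len(bx)
    se_fixed = np.sqrt(1.0 / np.sum(w * bx**2))
    se = se_fixed * max(1.0, np.sqrt(q / (n - 1)))
    return beta, se, q


def test_ivw_equals_wls_through_origin_oracle(ten_snp_instruments):
    est, het = ivw(ten_snp_instruments)
    bx = [h.beta_exposure for h in ten_snp_instruments]
    by = [h.beta_outcome for h in ten_snp_instruments]
    sy = [h.se_outcome for h in ten_snp_instruments]
    beta_o, se_o, q_o = ivw_wls_oracle(bx, by, sy)
    assert est.beta == pytest.approx(beta_o, abs=1e-10)
    assert est.se == pytest.approx(se_o, abs=1e-10)
    assert het.q == pytest.approx(q_o, abs=1e-10)


def test_ivw_identical_ratios_gives_zero_q():
    inst = make_instruments([0.1, 0.2, 0.05], [0.02, 0.04, 0.01], [0.01, 0.01, 0.01])
    est, het = ivw(inst)
    assert est.beta == pytest.approx(0.2)
    assert het.q == pytest.approx(0.0, abs=1e-20)
    assert het.pval == pytest.approx(1.0)
    # with Q = 0 the random-effects SE equals the fixed-effect SE
    w = np.array([0.1, 0.2, 0.05]) ** 2 / 0.01**2
    assert est.se == pytest.approx(1 / math.sqrt(w.sum()))


def test_ivw_random_effects_never_narrower_than_fixed(rng):
    for _ in range(20):
        n = rng.integers(3, 15)
        bx = rng.normal(0.05, 0.02, n)
        bx[bx == 0] = 0.01
        sy = rng.uniform(0.005, 0.02, n)
        by = rng.normal(0, 0.05, n)
        inst = make_instruments(bx, by, sy)
        est, _ = ivw(inst)
        _, w, _ = ratio_estimates(inst)
        se_fixed = 1 / math.sqrt(w.sum())
        assert est.se >= se_fixed - 1e-15


def test_ivw_requires_two_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        ivw(make_instruments([0.1], [0.02], [0.01]))


def test_estimate_ci_and_or_consistency(ten_snp_instruments):
    est, _ = ivw(ten_snp_instruments)
    assert est.ci_low < est.beta < est.ci_high
    orv, lo, hi = est.or_scale
    assert lo == pytest.approx(math.exp(est.ci_low), abs=1e-12)
    assert hi == pytest.approx(math.exp(est.ci_high), abs=1e-12)
    assert orv > 0


# --- MR-Egger ----------------------------------------------------------------

def egger_normal_equations_oracle(bx, by, sy):
    """Independent weighted normal equations with dispersion floored at 1
    and t(n-2) inference."""
    from scipy import stats
    bx, by, sy = map(np.asarray, (bx, by, sy))
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    XtWX = X.T @ (w[:, None] * X)
    XtWy = X.T @ (w * by)
    params = np.linalg.solve(XtWX, XtWy)
    resid = by - X @ params
    n = len(bx)
    sigma2 = (w * resid**2).sum() / (n - 2)
    cov = np.linalg.inv(XtWX) * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    return params[1], se[1], params[0], se[0]


def test_egger_matches_normal_equations_oracle(ten_snp_instruments):
    est = egger(ten_snp_instruments)
    bx = [h.beta_exposure for h in ten_snp_instruments]
    by = [h.beta_outcome for h in ten_snp_instruments]
    sy = [h.se_outcome for h in ten_snp_instruments]
    slope, slope_se, icpt, icpt_se = egger_normal_equations_oracle(bx, by, sy)
    assert est.beta == pytest.approx(slope, abs=1e-10)
    assert est.se == pytest.approx(slope_se, abs=1e-10)
    assert est.egger_intercept == pytest.approx(icpt, abs=1e-10)
    assert est.egger_intercept_se == pytest.approx(icpt_se, abs=1e-10)


def test_egger_exact_fit_zero_intercept():
    bx = np.array([0.05, 0.1, 0.15, 0.2])
    inst = make_instruments(bx, 0.3 * bx, [0.01] * 4)
    est = egger(inst)
    assert est.beta == pytest.approx(0.3, abs=1e-12)
    assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)


def test_egger_equals_ivw_when_intercept_constrained():
    """Zero-intercept WLS on the same weights reproduces the IVW slope."""
    inst = make_instruments([0.05, 0.08, 0.1, 0.13], [0.01, 0.03, 0.02, 0.04],
                            [0.01, 0.012, 0.009, 0.015])
    est_ivw, _ = ivw(inst)
    bx = np.array([h.beta_exposure for h in inst])
    by = np.array([h.beta_outcome for h in inst])
    w = 1.0 / np.array([h.se_outcome for h in inst]) ** 2
    slope_constrained = np.sum(w * bx * by) / np.sum(w * bx**2)
    assert est_ivw.beta == pytest.approx(slope_constrained, abs=1e-12)


def test_egger_requires_three():
    with pytest.raises(InsufficientInstrumentsError):
        egger(make_instruments([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))


def test_egger_orientation_invariance():
    """Sign-flipping a SNP's (bx, by) pair leaves Egger unchanged."""
    inst = make_instruments([0.05, -0.08, 0.1, 0.13], [0.01, 0.03, 0.02, 0.04],
                            [0.01, 0.012, 0.009, 0.015])
    flipped = make_instruments([0.05, 0.08, 0.1, 0.13], [0.01, -0.03, 0.02, 0.04],
                               [0.01, 0.012, 0.009, 0.015])
    a, b = egger(inst), egger(flipped)
    assert a.beta == pytest.approx(b.beta, abs=1e-12)
    assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-12)


# --- weighted median ---------------------------------------------------------

def weighted_median_bruteforce(ratios, weights):
    """Independent re-derivation from the definition: the point where the
    standardized mid-cumulative weight crosses one half, linearly
    interpolated between bracketing order statistics."""
    order = np.argsort(ratios)
    r = np.asarray(ratios)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return r[0]
    if 0.5 >= s[-1]:
        return r[-1]
    k = int(np.searchsorted(s, 0.5)) - 1
    frac = (0.5 - s[k]) / (s[k + 1] - s[k])
    return r[k] + frac * (r[k + 1] - r[k])


def test_weighted_median_equal_weights_is_median():
    inst = make_instruments([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], [0.01, 0.01, 0.01])
    est = weighted_median(inst, n_boot=50, seed=1)
    assert est.beta == pytest.approx(0.2)


def test_weighted_median_matches_bruteforce_on_six_snps(rng):
    bx = rng.normal(0.08, 0.02, 6)
    by = rng.normal(0.02, 0.01, 6)
    sy = rng.uniform(0.005, 0.02, 6)
    inst = make_instruments(bx, by, sy)
    est = weighted_median(inst, n_boot=50, seed=2)
    expected = weighted_median_bruteforce(by / bx, bx**2 / sy**2)
    assert est.beta == pytest.approx(expected, abs=1e-10)


def test_weighted_median_bootstrap_reproducible():
    inst = make_instruments([0.1, 0.12, 0.08, 0.09], [0.02, 0.01, 0.03, 0.02],
                            [0.01] * 4)
    a = weighted_median(inst, n_boot=200, seed=7)
    b = weighted_median(inst, n_boot=200, seed=7)
    assert a.se == b.se
    c = weighted_median(inst, n_boot=200, seed=8)
    assert a.se != c.se


def test_weighted_median_robust_to_30pct_invalid():
    """70% valid instruments at theta=0.2, 30% with gross pleiotropy:
    the weighted median stays within 3 bootstrap SEs of truth in nearly
    every replicate while the naive mean ratio is grossly biased."""
    theta = 0.2
    within, naive_bias = 0, []
    n_rep = 50
    for s in range(n_rep):
        r = np.random.default_rng(s)
        n = 20
        bx = r.normal(0.08, 0.01, n)
        sy = np.full(n, 0.004)
        by = theta * bx + r.normal(0, 1, n) * sy
        by[:6] += 0.08  # 30% invalid, large directional pleiotropy
        inst = make_instruments(bx, by, sy)
        est = weighted_median(inst, n_boot=100, seed=s)
        within += abs(est.beta - theta) < 3 * est.se
        naive_bias.append((by / bx).mean() - theta)
    assert within / n_rep >= 0.90
    assert np.mean(naive_bias) > 0.2  # naive mean absorbs the pleiotropy


# --- Cochran's Q -------------------------------------------------------------

def test_q_zero_for_homogeneous_ratios():
    inst = make_instruments([0.1, 0.2], [0.03, 0.06], [0.01, 0.01])
    het = cochran_q(inst, 0.3)
    assert het.q == pytest.approx(0.0, abs=1e-20)
    assert het.pval == pytest.approx(1.0)


def test_q_additive_over_disjoint_subsets(ten_snp_instruments):
    beta_ref = 0.25
    q_all = cochran_q(ten_snp_instruments, beta_ref).q
    q_a = cochran_q(ten_snp_instruments[:5], beta_ref).q
    q_b = cochran_q(ten_snp_instruments[5:], beta_ref).q
    assert q_all == pytest.approx(q_a + q_b, rel=1e-12)


def test_q_pvalue_uniform_under_null():
    """Under homogeneity, Q p-values are uniform (KS at alpha=0.01)."""
    from scipy import stats
    pvals = []
    for s in range(400):
        r = np.random.default_rng(s)
        n = 10
        bx = r.normal(0.08, 0.01, n)
        sy = np.full(n, 0.01)
        by = 0.1 * bx + r.normal(0, 1, n) * sy
        inst = make_instruments(bx, by, sy)
        est, het = ivw(inst)
        pvals.append(cochran_q(inst, est.beta).pval)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# --- leave-one-out -----------------------------------------------------------

def test_leave_one_out_counts_and_identity(ten_snp_instruments):
    loo = leave_one_out(ten_snp_instruments)
    assert len(loo) == 10
    assert {snp for snp, _, _ in loo} == {h.snp_id for h in ten_snp_instruments}


def test_leave_one_out_flags_planted_outlier():
    n = 12
    rng = np.random.default_rng(3)
    bx = rng.normal(0.1, 0.01, n)
    sy = np.full(n, 0.003)
    by = 0.2 * bx + rng.normal(0, 1, n) * sy
    by[4] += 0.15  # gross outlier
    inst = make_instruments(bx, by, sy)
    loo = leave_one_out(inst)
    flagged = [snp for snp, _, f in loo if f]
    assert "rs5" in flagged


def test_leave_one_out_identical_instruments():
    inst = make_instruments([0.1] * 5, [0.02] * 5, [0.01] * 5)
    full, _ = ivw(inst)
    for _, est, flag in leave_one_out(inst):
        assert est.beta == pytest.approx(full.beta)
        assert not flag


# --- rescaling ---------------------------------------------------------------

def test_rescale_identity_and_doubling(ten_snp_instruments):
    est, _ = ivw(ten_snp_instruments)
    same = rescale_estimate(est, 1.0, est.unit)
    assert same.beta == est.beta and same.se == est.se
    double = rescale_estimate(est, 2.0, "per 2 units")
    assert double.beta == pytest.approx(2 * est.beta)
    assert double.se == pytest.approx(2 * est.se)
    assert double.or_scale[0] == pytest.approx(est.or_scale[0] ** 2, rel=1e-12)
    assert double.pval == pytest.approx(est.pval, rel=1e-12)
    with pytest.raises(ValueError):
        rescale_estimate(est, 0.0, "bad")


def test_rescale_to_50pct_increase(ten_snp_instruments):
    est, _ = ivw(ten_snp_instruments)
    scaled = rescale_estimate(est, math.log(1.5), "per 50% increase")
    assert scaled.beta == pytest.approx(est.beta * math.log(1.5))


# --- equivariance property ---------------------------------------------------

@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10**6))
def test_all_estimators_negate_with_outcome(seed):
    r = np.random.default_rng(seed)
    n = 8
    bx = r.normal(0.08, 0.02, n)
    bx[np.abs(bx) < 1e-3] = 0.01
    sy = r.uniform(0.005, 0.02, n)
    by = r.normal(0.02, 0.02, n)
    inst = make_instruments(bx, by, sy)
    neg = make_instruments(bx, -by, sy)
    assert ivw(neg)[0].beta == pytest.approx(-ivw(inst)[0].beta, rel=1e-12)
    assert egger(neg).beta == pytest.approx(-egger(inst).beta, rel=1e-12)
    wm_pos = weighted_median(inst, n_boot=10, seed=seed).beta
    wm_neg = weighted_median(neg, n_boot=10, seed=seed).beta
    assert wm_neg == pytest.approx(-wm_pos, rel=1e-9, abs=1e-12)
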