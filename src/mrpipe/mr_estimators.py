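"""Core two-sample MR estimators and per-analysis diagnostics.

All estimators operate on harmonized instruments carrying
(beta_X, se_X, beta_Y, se_Y) per SNP.  The per-SNP causal estimate is
the Wald ratio beta_Y / beta_X with first-order weight
w_j = beta_X,j^2 / se_Y,j^2 (the inverse of the leading term of the
delta-method variance of the ratio).

* IVW: weighted mean of ratios; the multiplicative random-effects SE
  inflates the fixed-effect SE by sqrt(Q / (n - 1)) when Cochran's Q
  exceeds its degrees of freedom, and never deflates it.
* MR-Egger: weighted regression of beta_Y on beta_X with intercept
  (weights 1/se_Y^2), instruments oriented to beta_X >= 0; the
  intercept estimates the average directional pleiotropy and its
  p-value tests for it; inference uses t with n - 2 df and the
  residual variance floored at 1 (multiplicative over-dispersion).
* Weighted median: robust to up to 50% invalid weight, with a
  parametric-bootstrap SE.
* Cochran's Q, leave-one-out, and unit rescaling complete the
  per-analysis diagnostics.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from mrpipe.harmonization import HarmonizedInstrument

logger = logging.getLogger("mrpipe")

#: 95% normal quantile (exact)
Z95 = float(stats.norm.ppf(0.975))


class InsufficientInstrumentsError(ValueError):
    pass


@dataclasses.dataclass
class MrEstimate:
    """A causal-effect estimate on the log-odds scale, with its OR view."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    unit: str = "per exposure unit"
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))

    def to_row(self, **labels) -> dict:
        row = {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "OR": math.exp(self.beta),
            "ci_low": math.exp(self.ci_low),
            "ci_high": math.exp(self.ci_high),
            "pval": self.pval,
        }
        if self.egger_intercept_pval is not None:
            row["egger_intercept_pval"] = self.egger_intercept_pval
        row.update(labels)
        return row


@dataclasses.dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_exposure for h in instruments], dtype=float)
    sx = np.array([h.se_exposure for h in instruments], dtype=float)
    by = np.array([h.beta_outcome for h in instruments], dtype=float)
    sy = np.array([h.se_outcome for h in instruments], dtype=float)
    ids = [h.snp_id for h in instruments]
    return bx, sx, by, sy, ids


def ratio_estimates(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-SNP Wald ratios and first-order inverse-variance weights.

    SNPs with beta_X = 0 have an undefined ratio and are dropped with
    a warning.
    """
    bx, sx, by, sy, ids = _arrays(instruments)
    usable = bx != 0.0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("ratio_estimates: dropped %d SNPs with beta_X = 0", n_dropped)
    bx, by, sy = bx[usable], by[usable], sy[usable]
    ids = [i for i, u in zip(ids, usable) if u]
    if len(bx) < 1:
        raise InsufficientInstrumentsError("no usable instruments (all beta_X = 0)")
    ratios = by / bx
    weights = bx**2 / sy**2
    return ratios, weights, ids


def _normal_estimate(method, beta, se, n_snps, **extra) -> MrEstimate:
    z = beta / se
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(2.0 * stats.norm.sf(abs(z))),
        n_snps=n_snps,
        **extra,
    )


def wald_ratio(instrument: HarmonizedInstrument) -> MrEstimate:
    """Single-SNP causal estimate beta_Y / beta_X with first-order SE."""
    if instrument.beta_exposure == 0:
        raise InsufficientInstrumentsError(f"{instrument.snp_id}: beta_X = 0")
    beta = instrument.beta_outcome / instrument.beta_exposure
    se = instrument.se_outcome / abs(instrument.beta_exposure)
    return _normal_estimate("wald_ratio", beta, se, 1)


def ivw(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[MrEstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Equivalent to weighted least squares of beta_Y on beta_X through
    the origin with weights 1/se_Y^2.
    """
    if len(instruments) < 2:
        raise InsufficientInstrumentsError("IVW needs >= 2 instruments")
    ratios, w, _ = ratio_estimates(instruments)
    n = len(ratios)
    if n < 2:
        raise InsufficientInstrumentsError("IVW needs >= 2 usable instruments")
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    se_fixed = 1.0 / math.sqrt(np.sum(w))
    se = se_fixed * max(1.0, math.sqrt(q / (n - 1)))
    het = HeterogeneityResult(q=q, df=n - 1, pval=float(stats.chi2.sf(q, n - 1)))
    return _normal_estimate("ivw_re", beta, se, n), het


def egger(instruments: Sequence[HarmonizedInstrument]) -> MrEstimate:
    """MR-Egger regression: slope = causal effect, intercept = pleiotropy.

    Instruments are oriented so beta_X >= 0 (flipping both betas
    leaves the ratio unchanged); weights are 1/se_Y^2; parameter
    variances carry a multiplicative over-dispersion factor
    max(1, RSS/(n-2)); p-values from t with n - 2 df.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    bx, _, by, sy, _ = _arrays(instruments)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    n = len(bx)

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    # statsmodels scales by the estimated residual variance already;
    # floor the dispersion at 1 so the CI never narrows below the
    # fixed-effect (known-variance) one
    sigma2 = fit.scale  # RSS_w / (n - 2)
    inflate = max(1.0, sigma2) / sigma2
    bse = fit.bse * math.sqrt(inflate)
    params = fit.params

    tdist = stats.t(df=n - 2)
    tq = float(tdist.ppf(0.975))
    slope, slope_se = float(params[1]), float(bse[1])
    icpt, icpt_se = float(params[0]), float(bse[0])
    return MrEstimate(
        method="egger",
        beta=slope,
        se=slope_se,
        ci_low=slope - tq * slope_se,
        ci_high=slope + tq * slope_se,
        pval=float(2.0 * tdist.sf(abs(slope / slope_se))),
        n_snps=n,
        egger_intercept=icpt,
        egger_intercept_se=icpt_se,
        egger_intercept_pval=float(2.0 * tdist.sf(abs(icpt / icpt_se))),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with the midpoint (s_j - w_j/2) convention."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent as long as at least half of the weight comes from
    valid instruments.  Each bootstrap replicate redraws every
    (beta_X, beta_Y) from normals centered at the observed values
    with the reported SEs and recomputes the weighted median.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    bx, sx, by, sy, _ = _arrays(instruments)
    if np.any(bx == 0):
        keep = bx != 0
        bx, sx, by, sy = bx[keep], sx[keep], by[keep], sy[keep]
        if len(bx) < 3:
            raise InsufficientInstrumentsError("weighted median needs >= 3 usable instruments")
    ratios = by / bx
    weights = bx**2 / sy**2
    est = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    n = len(bx)
    bx_star = rng.normal(bx, sx, size=(n_boot, n))
    by_star = rng.normal(by, sy, size=(n_boot, n))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx_star[b]
        ok = bxs != 0
        r = by_star[b][ok] / bxs[ok]
        w = bxs[ok] ** 2 / sy[ok] ** 2
        boots[b] = _weighted_median(r, w)
    se = float(boots.std(ddof=1))
    return _normal_estimate("weighted_median", est, se, n)


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], beta: float
) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios around a reference estimate."""
    if len(instruments) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    ratios, w, _ = ratio_estimates(instruments)
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = len(ratios) - 1
    return HeterogeneityResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
) -> list[tuple[str, MrEstimate, bool]]:
    """IVW re-estimated with each SNP omitted in turn.

    Returns (omitted snp_id, estimate, influential) where a SNP is
    flagged influential if its omission flips the estimate's sign or
    moves it by more than the omitted-set estimate's SE.  The
    omitted-set SE is used because a gross outlier inflates the
    full-sample random-effects SE enough to mask its own influence.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full, _ = ivw(instruments)
    out = []
    for i, h in enumerate(instruments):
        rest = [x for j, x in enumerate(instruments) if j != i]
        est, _ = ivw(rest)
        influential = (
            np.sign(est.beta) != np.sign(full.beta) and full.beta != 0
        ) or abs(est.beta - full.beta) > est.se
        out.append((h.snp_id, est, bool(influential)))
    return out


def rescale_estimate(estimate: MrEstimate, factor: float, new_unit: str) -> MrEstimate:
    """Rescale to a new exposure unit (e.g. factor ln(1.5) for 'per 50% increase').

    Multiplies beta, SE and CI bounds; the z-score and p-value are
    unchanged.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    return dataclasses.replace(
        estimate,
        beta=estimate.beta * factor,
        se=estimate.se * factor,
        ci_low=estimate.ci_low * factor,
        ci_high=estimate.ci_high * factor,
        unit=new_unit,
    )
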