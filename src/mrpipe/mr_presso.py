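"""MR-PRESSO: pleiotropy residual sum and outlier framework.

Three linked tests on harmonized instruments:

Global test
    The observed residual sum of squares takes each SNP's residual
    against the IVW slope fitted with that SNP left out,
    RSS_obs = sum_j (beta_Y,j - b_{-j} beta_X,j)^2 / se_Y,j^2,
    and compares it with a parametric null built by redrawing
    beta_Y,j* ~ N(b_{-j} beta_X,j, se_Y,j^2) and
    beta_X,j* ~ N(beta_X,j, se_X,j^2) and recomputing the statistic
    n_sim times.

Outlier test
    Per-SNP p-value = fraction of simulated residual contributions at
    least as large as the observed one; SNPs significant after
    Bonferroni correction over the instruments tested are flagged and
    removed, giving the outlier-corrected IVW estimate.

Distortion test
    The relative change (b_corrected - b_all) / |b_corrected| is
    compared two-sidedly against a null built by removing random
    pseudo-outlier sets of the same size.

All Monte-Carlo p-values use the add-one correction (r + 1)/(n_sim + 1)
so they are never exactly zero; resolution is therefore ~1/n_sim.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from mrpipe.harmonization import HarmonizedInstrument
from mrpipe.mr_estimators import InsufficientInstrumentsError, MrEstimate, ivw

logger = logging.getLogger("mrpipe")


class DegenerateCorrectionError(ValueError):
    """Every instrument was flagged as an outlier."""


@dataclasses.dataclass
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outlier_ids: list[str]
    corrected: Optional[MrEstimate]
    distortion_pval: Optional[float]
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized.

    The IVW slope is sum(w bx by)/sum(w bx^2); dropping SNP j removes
    its terms from both sums.
    """
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Run the global, outlier and distortion tests.

    ``outlier_alpha`` is the familywise level; the per-SNP threshold
    is Bonferroni-corrected over the number of instruments tested.
    The distortion p-value is None when no outlier is flagged.
    """
    if len(instruments) < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")

    bx = np.array([h.beta_exposure for h in instruments])
    sx = np.array([h.se_exposure for h in instruments])
    by = np.array([h.beta_outcome for h in instruments])
    sy = np.array([h.se_outcome for h in instruments])
    ids = [h.snp_id for h in instruments]
    n = len(bx)
    w = 1.0 / sy**2

    slopes = _loo_slopes(bx, by, w)
    resid_obs = (by - slopes * bx) ** 2 * w
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, n))
    by_star = rng.normal(slopes * bx, sy, size=(n_sim, n))
    w_row = w[None, :]
    sxy = np.sum(w_row * bx_star * by_star, axis=1, keepdims=True)
    sxx = np.sum(w_row * bx_star**2, axis=1, keepdims=True)
    slopes_star = (sxy - w_row * bx_star * by_star) / (sxx - w_row * bx_star**2)
    resid_star = (by_star - slopes_star * bx_star) ** 2 * w_row
    rss_star = resid_star.sum(axis=1)

    global_pval = (np.sum(rss_star >= rss_obs) + 1.0) / (n_sim + 1.0)

    per_snp_p = (np.sum(resid_star >= resid_obs[None, :], axis=0) + 1.0) / (n_sim + 1.0)
    outlier_pvals = dict(zip(ids, per_snp_p.astype(float)))
    bonf = outlier_alpha / n
    flagged = [ids[j] for j in range(n) if per_snp_p[j] < bonf]

    if len(flagged) == n:
        raise DegenerateCorrectionError("all instruments flagged as outliers")

    corrected: Optional[MrEstimate] = None
    distortion_pval: Optional[float] = None
    if flagged:
        keep = [h for h in instruments if h.snp_id not in set(flagged)]
        corrected, _ = ivw(keep)
        beta_all, _ = ivw(instruments)
        if corrected.beta != 0:
            d_obs = (corrected.beta - beta_all.beta) / abs(corrected.beta)
            # null: random pseudo-outlier sets of the same size
            k = len(flagged)
            d_null = np.empty(n_sim)
            idx = np.arange(n)
            for s in range(n_sim):
                drop = rng.choice(idx, size=k, replace=False)
                mask = np.ones(n, dtype=bool)
                mask[drop] = False
                b = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
                d_null[s] = (b - beta_all.beta) / abs(b) if b != 0 else np.inf
            distortion_pval = float(
                (np.sum(np.abs(d_null) >= abs(d_obs)) + 1.0) / (n_sim + 1.0)
            )
        logger.info(
            "presso: flagged %d/%d outliers (%s), distortion p=%s",
            len(flagged), n, flagged, distortion_pval,
        )

    return PressoResult(
        global_rss=rss_obs,
        global_pval=float(global_pval),
        outlier_pvals=outlier_pvals,
        outlier_ids=flagged,
        corrected=corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )
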