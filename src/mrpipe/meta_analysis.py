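"""Fixed-effect inverse-variance meta-analysis across cohorts.

Per-cohort causal estimates (log-odds scale) are pooled with weights
1/se^2; between-study heterogeneity is summarized by Q and
I^2 = max(0, (Q - (k-1))/Q) * 100, banded at the conventional
25/50/75 cutpoints (low / medium / high / extreme).

``from_ci`` converts printed odds ratios with 95% confidence intervals
into (beta, se) pairs using the 1.96 convention, so published
per-cohort tables can be pooled directly.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("mrpipe")

#: printed-table convention for 95% intervals (CI -> SE conversion)
Z_PRINTED = 1.96
#: exact normal quantile for CIs the package computes itself
Z95 = float(stats.norm.ppf(0.975))

I2_BANDS = ((25.0, "low"), (50.0, "medium"), (75.0, "high"))


@dataclasses.dataclass
class MetaResult:
    beta_combined: float
    se_combined: float
    ci_low: float
    ci_high: float
    pval: float
    q_meta: float
    i2: float
    i2_band: str
    cohorts: list[str]

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return (
            math.exp(self.beta_combined),
            math.exp(self.ci_low),
            math.exp(self.ci_high),
        )


def i2_band(i2: float) -> str:
    if i2 < 25.0:
        return "low"
    if i2 < 50.0:
        return "medium"
    if i2 < 75.0:
        return "high"
    return "extreme"


def from_ci(
    point: float, ci: tuple[float, float], scale: str = "or"
) -> tuple[float, float]:
    """Recover (beta, se) from a printed point estimate and 95% CI.

    ``scale='or'`` log-transforms first.  se = (log upper - log
    lower) / (2 * 1.96), matching how published tables are built.
    """
    lo, hi = ci
    if scale == "or":
        if point <= 0 or lo <= 0 or hi <= 0:
            raise ValueError("OR-scale values must be positive")
        beta, lo, hi = math.log(point), math.log(lo), math.log(hi)
    elif scale == "log":
        beta = point
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if not lo <= beta <= hi:
        raise ValueError(f"CI ({lo}, {hi}) does not bracket the point {beta}")
    se = (hi - lo) / (2.0 * Z_PRINTED)
    if se <= 0:
        raise ValueError("degenerate CI: se must be > 0")
    return beta, se


def fixed_effect_meta(
    estimates: Sequence[tuple[float, float]],
    cohorts: Sequence[str] | None = None,
) -> MetaResult:
    """Pool (beta, se) pairs with fixed-effect inverse-variance weights."""
    if len(estimates) < 1:
        raise ValueError("no estimates to pool")
    if cohorts is None:
        cohorts = [f"study_{i + 1}" for i in range(len(estimates))]
    if len(estimates) == 1:
        logger.warning("fixed_effect_meta: single estimate, passing through")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be > 0")

    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    k = len(betas)
    q = float(np.sum(w * (betas - beta) ** 2))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    z = beta / se
    return MetaResult(
        beta_combined=beta,
        se_combined=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=float(2.0 * stats.norm.sf(abs(z))),
        q_meta=q,
        i2=i2,
        i2_band=i2_band(i2),
        cohorts=list(cohorts),
    )
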