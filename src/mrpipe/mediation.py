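"""Two-step MR mediation by the product-of-coefficients method.

For an exposure -> mediator -> outcome triple, three univariable MR
fits provide:

* the total effect of exposure on outcome,
* direct effect A: exposure on mediator (exposure's instruments),
* direct effect B: mediator on outcome (the mediator's own
  instruments).

The indirect effect is A x B; the mediated proportion is
indirect / total.  The indirect-effect SE uses the first-order delta
method sqrt(A^2 sB^2 + B^2 sA^2) with no covariance term — the two
steps come from non-overlapping instrument-outcome regressions in
two-sample MR.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional

import pandas as pd

from mrpipe.harmonization import harmonize
from mrpipe.instrument_selection import select_instruments
from mrpipe.mr_estimators import InsufficientInstrumentsError, Z95, ivw
from mrpipe.sumstats_io import GwasTable, RunConfig

logger = logging.getLogger("mrpipe")


@dataclasses.dataclass
class MediationResult:
    """Total / direct / indirect effects for one mediation triple.

    ``proportion`` is indirect/total (a fraction; multiply by 100 for
    the percentage).  It is reported even when it falls outside [0, 1]
    or the indirect and total effects disagree in sign — the
    ``inconsistent`` flag marks such cases rather than suppressing
    them.
    """

    total_effect: float
    total_se: float
    direct_a: float
    direct_a_se: float
    direct_b: float
    direct_b_se: float
    indirect: float
    se_indirect: float
    ci_indirect: tuple[float, float]
    proportion: Optional[float]
    inconsistent: bool
    exposure: str = "exposure"
    mediator: str = "mediator"
    outcome: str = "outcome"
    cohort: str = ""

    @property
    def proportion_pct(self) -> Optional[int]:
        """Mediated proportion as an integer percentage (table convention)."""
        if self.proportion is None:
            return None
        return int(round(self.proportion * 100.0))

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "cohort": self.cohort,
            "total_effect": self.total_effect,
            "direct_effect_A": self.direct_a,
            "direct_effect_B": self.direct_b,
            "mediation_effect": self.indirect,
            "mediated_proportion_pct": self.proportion_pct,
            "inconsistent": self.inconsistent,
        }


def two_step_mediation(
    total: tuple[float, float],
    step_a: tuple[float, float],
    step_b: tuple[float, float],
    **labels,
) -> MediationResult:
    """Combine three (beta, se) pairs into a mediation decomposition.

    ``total`` is the exposure->outcome effect, ``step_a`` the
    exposure->mediator effect, ``step_b`` the mediator->outcome
    effect.  When the total effect is zero the proportion is
    undefined (None) but the indirect effect is still reported.
    """
    bt, st = total
    ba, sa = step_a
    bb, sb = step_b
    for name, s in (("total", st), ("step_a", sa), ("step_b", sb)):
        if s < 0:
            raise ValueError(f"{name}: se must be >= 0, got {s}")

    indirect = ba * bb
    se_ind = math.sqrt(ba**2 * sb**2 + bb**2 * sa**2)
    if bt != 0:
        proportion = indirect / bt
        inconsistent = proportion < 0 or proportion > 1
    else:
        logger.warning("two_step_mediation: total effect is 0, proportion undefined")
        proportion = None
        inconsistent = True
    return MediationResult(
        total_effect=bt,
        total_se=st,
        direct_a=ba,
        direct_a_se=sa,
        direct_b=bb,
        direct_b_se=sb,
        indirect=indirect,
        se_indirect=se_ind,
        ci_indirect=(indirect - Z95 * se_ind, indirect + Z95 * se_ind),
        proportion=proportion,
        inconsistent=inconsistent,
        **labels,
    )


def _ivw_step(
    exposure: GwasTable,
    outcome: GwasTable,
    config: RunConfig,
    ld: Optional[pd.DataFrame],
    step_name: str,
    p_threshold: Optional[float] = None,
) -> tuple[float, float]:
    """One univariable MR fit: select instruments, harmonize, IVW."""
    p_thr = p_threshold if p_threshold is not None else config.p_threshold
    selected = select_instruments(
        exposure, p_thr, ld=ld, clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
    )
    instruments, _ = harmonize(
        selected.table, outcome, policy=config.palindrome_policy,
        ambiguity_band=config.eaf_ambiguity_band,
    )
    if len(instruments) < 2:
        raise InsufficientInstrumentsError(
            f"{step_name}: fewer than 2 instruments after harmonization"
        )
    est, _ = ivw(instruments)
    logger.info("%s: IVW beta=%.4g se=%.4g on %d SNPs", step_name, est.beta, est.se, est.n_snps)
    return est.beta, est.se


def mediation_pipeline(
    exposure: GwasTable,
    mediator: GwasTable,
    outcome: GwasTable,
    config: RunConfig,
    ld: Optional[pd.DataFrame] = None,
    mediator_p_threshold: Optional[float] = None,
) -> MediationResult:
    """Full two-step MR on three summary-statistic tables.

    Step A regresses the mediator on the exposure's instruments,
    step B the outcome on the mediator's own instruments, and the
    total effect the outcome on the exposure's instruments; each step
    runs the configured selection and harmonization.
    """
    total = _ivw_step(exposure, outcome, config, ld, "total (exposure->outcome)")
    step_a = _ivw_step(exposure, mediator, config, ld, "step A (exposure->mediator)")
    step_b = _ivw_step(
        mediator, outcome, config, ld, "step B (mediator->outcome)",
        p_threshold=mediator_p_threshold,
    )
    return two_step_mediation(
        total, step_a, step_b,
        exposure=exposure.trait_name,
        mediator=mediator.trait_name,
        outcome=outcome.trait_name,
    )
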