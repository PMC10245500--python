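"""Align exposure and outcome summary statistics to a shared effect allele.

Each instrument SNP present in both tables is matched under four
interpretations, tried in order: same alleles same order (keep as is),
swapped alleles (flip the outcome beta's sign and complement its
frequency), complementary-strand alleles (recode, then apply the same
swap logic).  SNPs reconcilable under none of these are dropped with a
reason code.

Palindromic SNPs (A/T or C/G pairs) are a special case: the strand
recode reproduces the swapped pair, so allele labels alone cannot
orient them.  Two policies are provided:

``drop_all``
    remove every palindromic SNP;
``eaf_infer``
    orient by comparing the effect-allele frequency to 0.5 on both
    sides, dropping SNPs whose frequency on either side falls inside
    the configured ambiguity band (default 0.42-0.58), where the
    comparison is uninformative.

Indel alleles are never treated as palindromic.  Missing SNPs are not
proxied — instruments absent from the outcome are simply dropped and
counted.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import Counter

import pandas as pd

from mrpipe.sumstats_io import GwasTable

logger = logging.getLogger("mrpipe")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

AS_IS = "as_is"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
STRAND_AND_SIGN_FLIPPED = "strand_flipped_and_sign_flipped"


@dataclasses.dataclass(frozen=True)
class HarmonizedInstrument:
    """One SNP aligned to the exposure's effect allele."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float
    eaf_outcome: float
    action_taken: str

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be > 0")


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT[b] for b in allele)


def _is_palindromic(a1: str, a2: str) -> bool:
    if len(a1) != 1 or len(a2) != 1:
        return False  # indels: strand ambiguity does not apply
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _ambiguous(eaf: float, band: tuple[float, float]) -> bool:
    lo, hi = band
    return lo < eaf < hi


def harmonize(
    exposure: GwasTable,
    outcome: GwasTable,
    policy: str = "eaf_infer",
    ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> tuple[list[HarmonizedInstrument], Counter]:
    """Harmonize outcome records onto the exposure's allele coding.

    Returns the aligned instruments plus a Counter of drop reasons
    (``missing_in_outcome``, ``palindromic_dropped``,
    ``palindromic_ambiguous``, ``irreconcilable_alleles``).
    """
    if policy not in ("drop_all", "eaf_infer"):
        raise ValueError(f"unknown palindrome policy {policy!r}")

    out_by_id = {r.snp_id: r for r in outcome.records}
    harmonized: list[HarmonizedInstrument] = []
    drops: Counter = Counter()

    for exp in exposure.records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            drops["missing_in_outcome"] += 1
            continue

        e1, e2 = exp.effect_allele, exp.other_allele
        o1, o2 = out.effect_allele, out.other_allele

        if _is_palindromic(e1, e2):
            if {o1, o2} != {e1, e2}:
                drops["irreconcilable_alleles"] += 1
                continue
            if policy == "drop_all":
                drops["palindromic_dropped"] += 1
                continue
            # eaf_infer: orient by which side of 0.5 the frequency falls
            if math.isnan(exp.eaf) or math.isnan(out.eaf):
                drops["palindromic_ambiguous"] += 1
                continue
            if _ambiguous(exp.eaf, ambiguity_band) or _ambiguous(out.eaf, ambiguity_band):
                drops["palindromic_ambiguous"] += 1
                continue
            # frequency of the exposure effect allele in the outcome study:
            # reported for o1; on either strand reading, label o1 matches e1
            # frequency-wise iff the two reported frequencies agree in side.
            same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
            if same_side:
                harmonized.append(
                    HarmonizedInstrument(
                        exp.snp_id, exp.beta, exp.se, out.beta, out.se,
                        exp.eaf, out.eaf, AS_IS,
                    )
                )
            else:
                harmonized.append(
                    HarmonizedInstrument(
                        exp.snp_id, exp.beta, exp.se, -out.beta, out.se,
                        exp.eaf, 1.0 - out.eaf, SIGN_FLIPPED,
                    )
                )
            continue

        # non-palindromic: try direct, swapped, then strand-recoded matches
        action = None
        if (o1, o2) == (e1, e2):
            action = AS_IS
        elif (o1, o2) == (e2, e1):
            action = SIGN_FLIPPED
        else:
            try:
                c1, c2 = _complement(o1), _complement(o2)
            except KeyError:
                c1 = c2 = None
            if (c1, c2) == (e1, e2):
                action = STRAND_FLIPPED
            elif (c1, c2) == (e2, e1):
                action = STRAND_AND_SIGN_FLIPPED
        if action is None:
            drops["irreconcilable_alleles"] += 1
            continue

        sign = -1.0 if action in (SIGN_FLIPPED, STRAND_AND_SIGN_FLIPPED) else 1.0
        eaf_out = out.eaf if sign > 0 else (1.0 - out.eaf if not math.isnan(out.eaf) else out.eaf)
        harmonized.append(
            HarmonizedInstrument(
                exp.snp_id, exp.beta, exp.se, sign * out.beta, out.se,
                exp.eaf, eaf_out, action,
            )
        )

    logger.info(
        "harmonize: %d/%d instruments aligned (%s)",
        len(harmonized), len(exposure.df), dict(drops) or "no drops",
    )
    return harmonized, drops


def instruments_to_frame(instruments: list[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabular view with the action_taken audit column."""
    return pd.DataFrame([dataclasses.asdict(h) for h in instruments])


def frame_to_instruments(df: pd.DataFrame) -> list[HarmonizedInstrument]:
    return [
        HarmonizedInstrument(
            snp_id=str(r.snp_id),
            beta_exposure=float(r.beta_exposure),
            se_exposure=float(r.se_exposure),
            beta_outcome=float(r.beta_outcome),
            se_outcome=float(r.se_outcome),
            eaf_exposure=float(r.eaf_exposure),
            eaf_outcome=float(r.eaf_outcome),
            action_taken=str(r.action_taken),
        )
        for r in df.itertuples(index=False)
    ]
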