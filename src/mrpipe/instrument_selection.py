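"""Instrument selection: significance filter, LD clumping, instrument strength.

Instruments are SNPs passing a genome-wide significance threshold
(strictly p < threshold) that survive greedy LD clumping: iterating in
ascending p-value order, a SNP is kept only if no already-kept SNP on
the same chromosome within the clumping window has LD r^2 at or above
the cutoff.  Instrument strength is summarized by the F-statistic

    F = R^2 (N - k - 1) / (k (1 - R^2))

with R^2 the summed variance explained, N the exposure GWAS sample
size and k the number of instruments.  Per-SNP variance explained uses
the standardized-trait approximation 2 p (1 - p) beta^2.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from mrpipe.sumstats_io import GwasTable

logger = logging.getLogger("mrpipe")

#: conventional weak-instrument rule of thumb
F_WEAK_THRESHOLD = 10.0


class LdMatrixError(ValueError):
    pass


@dataclasses.dataclass
class InstrumentSet:
    """Selected instruments with strength summaries."""

    table: GwasTable
    r2_total: float
    f_statistic: float
    per_snp_f: pd.Series
    weak_instruments: bool


def select_by_pvalue(table: GwasTable, p_threshold: float) -> GwasTable:
    """Keep SNPs with p strictly below the threshold, order preserved."""
    df = table.df[table.df["pval"] < p_threshold].reset_index(drop=True)
    logger.info(
        "%s: %d/%d SNPs pass p < %g", table.trait_name, len(df), len(table.df), p_threshold
    )
    if df.empty:
        logger.warning("%s: no SNPs pass p < %g", table.trait_name, p_threshold)
    return GwasTable(table.trait_name, table.trait_unit, df)


def _validate_ld(ld: pd.DataFrame) -> None:
    vals = ld.to_numpy(dtype=float)
    if vals.shape[0] != vals.shape[1]:
        raise LdMatrixError("LD matrix must be square")
    if not np.allclose(vals, vals.T, atol=1e-8):
        raise LdMatrixError("LD matrix must be symmetric")
    if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12:
        raise LdMatrixError("LD r^2 entries must lie in [0, 1]")


def clump(
    table: GwasTable,
    ld: pd.DataFrame | None,
    clump_r2: float,
    clump_window_kb: float,
) -> GwasTable:
    """Greedy LD clumping by ascending p-value.

    Ties on p are broken by (chrom, pos, snp_id) so the result is
    deterministic and invariant to input row order.  SNP pairs absent
    from the LD matrix are treated as independent (r^2 = 0) with a
    warning — real analyses fall back to an external reference panel
    that is not shipped here.
    """
    if ld is not None:
        _validate_ld(ld)
    df = table.df
    order = df.sort_values(
        ["pval", "chrom", "pos", "snp_id"], kind="mergesort"
    ).index.to_numpy()

    window_bp = clump_window_kb * 1000.0
    kept: list[int] = []
    missing_pairs = 0
    for i in order:
        row = df.loc[i]
        ok = True
        for j in kept:
            other = df.loc[j]
            if row["chrom"] != other["chrom"]:
                continue
            if abs(int(row["pos"]) - int(other["pos"])) > window_bp:
                continue
            if ld is not None and row["snp_id"] in ld.index and other["snp_id"] in ld.columns:
                r2 = float(ld.at[row["snp_id"], other["snp_id"]])
            else:
                r2 = 0.0
                missing_pairs += 1
            if r2 >= clump_r2:
                ok = False
                break
        if ok:
            kept.append(i)
    if missing_pairs:
        logger.warning("clump: %d SNP pairs absent from LD matrix, assumed r^2 = 0", missing_pairs)

    out = df.loc[sorted(kept)].reset_index(drop=True)
    logger.info("%s: clumping kept %d/%d SNPs", table.trait_name, len(out), len(df))
    return GwasTable(table.trait_name, table.trait_unit, out)


def snp_r2(beta: float, eaf: float) -> float:
    """Variance in a standardized phenotype explained by one SNP: 2p(1-p)beta^2."""
    if not 0 < eaf < 1:
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    return 2.0 * eaf * (1.0 - eaf) * beta**2


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Overall instrument F: R^2 (N - k - 1) / (k (1 - R^2))."""
    if not 0 <= r2_total < 1:
        raise ValueError(f"r2_total must be in [0, 1), got {r2_total}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1, got n={n}, k={k}")
    return r2_total * (n - k - 1) / (k * (1.0 - r2_total))


def select_instruments(
    table: GwasTable,
    p_threshold: float,
    ld: pd.DataFrame | None = None,
    clump_r2: float = 0.01,
    clump_window_kb: float = 10_000.0,
    study_n: int | None = None,
) -> InstrumentSet:
    """Full selection: p-value filter, clumping, strength summaries.

    ``study_n`` is the exposure GWAS sample size entering F; when not
    given, the maximum per-SNP n is used (summary files often report
    'up to N' sample sizes).
    """
    sig = table.df[table.df["pval"] < p_threshold].reset_index(drop=True)
    if sig.empty:
        raise ValueError(
            f"{table.trait_name}: no SNPs pass p < {p_threshold}; cannot build instrument set"
        )
    sig_table = GwasTable(table.trait_name, table.trait_unit, sig)
    clumped = clump(sig_table, ld, clump_r2, clump_window_kb)

    df = clumped.df
    per_r2 = np.array([snp_r2(b, f) for b, f in zip(df["beta"], df["eaf"])])
    r2_total = float(per_r2.sum())
    k = len(df)
    n = int(study_n if study_n is not None else df["n"].max())
    f_all = f_statistic(r2_total, n, k)
    per_f = pd.Series(
        [f_statistic(r, n, 1) for r in per_r2], index=df["snp_id"].to_numpy(), name="F"
    )
    return InstrumentSet(
        table=clumped,
        r2_total=r2_total,
        f_statistic=f_all,
        per_snp_f=per_f,
        weak_instruments=f_all <= F_WEAK_THRESHOLD,
    )
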