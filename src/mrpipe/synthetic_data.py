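"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator simulates summary statistics directly — no individual-level
genotypes — under the standard two-sample MR model.  For SNP j with
minor-allele frequency p_j and true SNP->exposure effect gamma_j,

    sigma_X,j = 1 / sqrt(2 p_j (1 - p_j) N_X)        (standardized trait)
    beta_X,j ~ Normal(gamma_j, sigma_X,j^2)
    beta_Y,j ~ Normal(theta * gamma_j + alpha_j, sigma_Y,j^2)

where theta is the causal effect and alpha_j a direct (pleiotropic)
effect on the outcome.  Pleiotropy modes: ``none`` (alpha = 0),
``balanced`` (mean-zero), ``directional`` (non-zero mean, InSIDE holds),
``inside_violated`` (alpha correlated with gamma through a Gaussian
copula).  Binary-outcome effects are treated as log-odds with normal
sampling error, matching how FinnGen / UK Biobank log-ORs are consumed.

Allele handling mimics real cross-consortium files: a configurable
fraction of SNPs get complementary (palindromic) allele pairs, a
fraction of outcome rows are reported on the opposite strand, and a
fraction are missing from the outcome table altogether.  The LD matrix
is block-diagonal with r^2 = ld_rho^|i-j| inside a block and zero
across blocks; LD is generated independently of effect sizes so that
clumping is exercised structurally.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from mrpipe.sumstats_io import GwasTable, STANDARD_COLUMNS

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# non-palindromic ordered allele pairs to draw from
_NONPAL_PAIRS = [
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameterization of a synthetic two-sample MR dataset.

    Defaults emulate a well-powered anthropometric exposure GWAS
    (~200k samples, ~30 independent hits of mean effect 0.03 SD per
    allele) against a biobank-scale binary-outcome GWAS (~100k
    samples), with a realistic share of palindromic (15%) and
    strand-flipped (10%) variants and 5% of instruments missing from
    the outcome file.
    """

    n_snps: int = 30
    theta: float = 0.2
    gamma_mean: float = 0.03
    gamma_sd: float = 0.008
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violated
    alpha_mean: float = 0.0
    alpha_sd: float = 0.002
    alpha_gamma_corr: float = 0.0
    n_exposure: int = 200_000
    n_outcome: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.15
    frac_strand_flipped: float = 0.10
    frac_missing_in_outcome: float = 0.05
    ld_block_size: int = 1
    ld_rho: float = 0.4
    # mediator-specific instruments (used by simulate_mediation_triple):
    # SNPs that act on the mediator directly, not through the exposure
    n_mediator_snps: int = 0
    delta_mean: float = 0.03
    delta_sd: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_palindromic", "frac_strand_flipped", "frac_missing_in_outcome"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_snps < 3:
            raise ConfigError("n_snps must be >= 3")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ConfigError("sample sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violated"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError("ld_rho must be in [0, 1)")


@dataclasses.dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth that produced them."""

    exposure_table: GwasTable
    outcome_table: GwasTable
    ld_matrix: pd.DataFrame
    truth: dict
    mediator_table: Optional[GwasTable] = None


def _draw_alpha(rng: np.random.Generator, cfg: SimulationConfig, gamma: np.ndarray) -> np.ndarray:
    n = len(gamma)
    if cfg.pleiotropy_mode == "none":
        return np.zeros(n)
    if cfg.pleiotropy_mode == "balanced":
        return rng.normal(0.0, cfg.alpha_sd, n)
    if cfg.pleiotropy_mode == "directional":
        return rng.normal(cfg.alpha_mean, cfg.alpha_sd, n)
    # inside_violated: Gaussian-copula correlation with gamma
    rho = cfg.alpha_gamma_corr
    z_gamma = (gamma - cfg.gamma_mean) / max(cfg.gamma_sd, 1e-300)
    z_indep = rng.normal(0.0, 1.0, n)
    z_alpha = rho * z_gamma + np.sqrt(max(0.0, 1.0 - rho**2)) * z_indep
    return cfg.alpha_mean + cfg.alpha_sd * z_alpha


def _assign_positions(n: int, block: int) -> tuple[np.ndarray, np.ndarray]:
    """Chrom/pos layout: one LD block per locus, loci far apart.

    Blocks cycle through chromosomes 1..22; consecutive blocks on the
    same chromosome are 20 Mb apart (beyond any standard clumping
    window), SNPs inside a block sit 10 kb apart.
    """
    idx = np.arange(n)
    block_id = idx // block
    within = idx % block
    chrom = (block_id % 22) + 1
    locus = block_id // 22
    pos = 1_000_000 + locus * 20_000_000 + within * 10_000
    return chrom.astype(str), pos.astype(int)


def _allele_pairs(rng: np.random.Generator, n: int, frac_pal: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_pal = int(round(frac_pal * n))
    is_pal = np.zeros(n, dtype=bool)
    is_pal[rng.choice(n, size=n_pal, replace=False)] = True
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for j in range(n):
        pool = _PAL_PAIRS if is_pal[j] else _NONPAL_PAIRS
        a1, a2 = pool[rng.integers(len(pool))]
        ea[j], oa[j] = a1, a2
    return ea, oa, is_pal


def _ld_matrix(snp_ids: list[str], cfg: SimulationConfig) -> pd.DataFrame:
    n = len(snp_ids)
    mat = np.zeros((n, n))
    block = cfg.ld_block_size
    for start in range(0, n, block):
        stop = min(start + block, n)
        size = stop - start
        i, j = np.indices((size, size))
        mat[start:stop, start:stop] = cfg.ld_rho ** np.abs(i - j)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=snp_ids, columns=snp_ids)


def _gwas_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    # keep p in (0, 1] so the table validates
    return np.clip(p, 5e-324, 1.0)


def _make_table(name, unit, snp_ids, chrom, pos, ea, oa, eaf, beta, se, n) -> GwasTable:
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": n,
        }
    )[STANDARD_COLUMNS]
    return GwasTable(name, unit, df)


def simulate_two_sample(config: SimulationConfig) -> SyntheticDataset:
    """Generate exposure and outcome summary statistics plus LD and truth.

    Identical config (including seed) gives byte-identical tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps

    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, n) if hi > lo else np.full(n, lo)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, n)
    alpha = _draw_alpha(rng, cfg, gamma)

    se_x = _gwas_se(maf, cfg.n_exposure)
    se_y = _gwas_se(maf, cfg.n_outcome)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.theta * gamma + alpha, se_y)

    snp_ids = [f"rs{j + 1:06d}" for j in range(n)]
    chrom, pos = _assign_positions(n, cfg.ld_block_size)
    ea, oa, is_pal = _allele_pairs(rng, n, cfg.frac_palindromic)

    exposure = _make_table(
        "exposure", "SD", snp_ids, chrom, pos, ea, oa, maf.copy(), beta_x, se_x,
        np.full(n, cfg.n_exposure),
    )

    # outcome table: strand flips, then drop the missing fraction
    ea_out = ea.copy()
    oa_out = oa.copy()
    n_flip = int(round(cfg.frac_strand_flipped * n))
    flip_idx = rng.choice(n, size=n_flip, replace=False)
    for j in flip_idx:
        ea_out[j] = _COMPLEMENT[ea_out[j]]
        oa_out[j] = _COMPLEMENT[oa_out[j]]
    # small cross-cohort frequency noise, as between real consortia
    eaf_out = np.clip(maf + rng.normal(0.0, 0.005, n), 0.001, 0.999)

    n_missing = int(round(cfg.frac_missing_in_outcome * n))
    missing_idx = rng.choice(n, size=n_missing, replace=False)
    keep = np.setdiff1d(np.arange(n), missing_idx)

    outcome = _make_table(
        "outcome", "log-odds",
        [snp_ids[j] for j in keep], chrom[keep], pos[keep],
        ea_out[keep], oa_out[keep], eaf_out[keep], beta_y[keep], se_y[keep],
        np.full(len(keep), cfg.n_outcome),
    )

    invalid = np.nonzero(alpha != 0.0)[0]
    truth = {
        "theta": cfg.theta,
        "gamma": gamma,
        "alpha": alpha,
        "maf": maf,
        "snp_ids": snp_ids,
        "invalid_idx": invalid,
        "palindromic_idx": np.nonzero(is_pal)[0],
        "strand_flipped_idx": np.sort(flip_idx),
        "missing_idx": np.sort(missing_idx),
    }
    return SyntheticDataset(
        exposure_table=exposure,
        outcome_table=outcome,
        ld_matrix=_ld_matrix(snp_ids, cfg),
        truth=truth,
    )


def simulate_mediation_triple(
    config: SimulationConfig,
    beta_em: float,
    beta_mo: float,
    theta_direct: float = 0.0,
) -> SyntheticDataset:
    """Generate an exposure / mediator / outcome triple for two-step MR.

    The exposure's instruments act on the mediator through the
    exposure (``beta_em`` per exposure SD) and on the outcome both
    directly (``theta_direct``) and through the mediator
    (``beta_mo``), so the true total effect is
    ``theta_direct + beta_em * beta_mo`` and the true mediated
    proportion is ``beta_em * beta_mo / total``.

    ``config.n_mediator_snps`` extra SNPs act on the mediator only
    (effects drawn Normal(delta_mean, delta_sd)) and reach the outcome
    solely through the mediator.  These give the mediator its own
    instrument set for step B, as in real two-step MR where the
    mediator GWAS contributes hits independent of the exposure.
    All SNPs appear in all three tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    n_e = cfg.n_snps
    n_m = cfg.n_mediator_snps
    n = n_e + n_m

    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, n) if hi > lo else np.full(n, lo)
    gamma = np.zeros(n)
    gamma[:n_e] = rng.normal(cfg.gamma_mean, cfg.gamma_sd, n_e)
    delta = np.zeros(n)
    if n_m:
        delta[n_e:] = rng.normal(cfg.delta_mean, cfg.delta_sd, n_m)
    alpha = _draw_alpha(rng, cfg, gamma)

    # true per-SNP effects
    mu_m = beta_em * gamma + delta
    mu_y = theta_direct * gamma + beta_mo * mu_m + alpha

    se_x = _gwas_se(maf, cfg.n_exposure)
    se_m = _gwas_se(maf, cfg.n_exposure)  # mediator GWAS of comparable size
    se_y = _gwas_se(maf, cfg.n_outcome)
    beta_x = rng.normal(gamma, se_x)
    beta_m = rng.normal(mu_m, se_m)
    beta_y = rng.normal(mu_y, se_y)

    snp_ids = [f"rs{j + 1:06d}" for j in range(n)]
    chrom, pos = _assign_positions(n, cfg.ld_block_size)
    ea, oa, is_pal = _allele_pairs(rng, n, cfg.frac_palindromic)
    n_arr = np.full(n, cfg.n_exposure)

    exposure = _make_table("exposure", "SD", snp_ids, chrom, pos, ea, oa, maf.copy(), beta_x, se_x, n_arr)
    mediator = _make_table("mediator", "SD", snp_ids, chrom, pos, ea, oa, maf.copy(), beta_m, se_m, n_arr)
    outcome = _make_table(
        "outcome", "log-odds", snp_ids, chrom, pos, ea, oa, maf.copy(), beta_y, se_y,
        np.full(n, cfg.n_outcome),
    )

    total = theta_direct + beta_em * beta_mo
    truth = {
        "theta": total,
        "theta_direct": theta_direct,
        "beta_em": beta_em,
        "beta_mo": beta_mo,
        "total": total,
        "indirect": beta_em * beta_mo,
        "proportion": (beta_em * beta_mo / total) if total != 0 else float("nan"),
        "gamma": gamma,
        "delta": delta,
        "alpha": alpha,
        "snp_ids": snp_ids,
        "invalid_idx": np.nonzero(alpha != 0.0)[0],
        "palindromic_idx": np.nonzero(is_pal)[0],
    }
    return SyntheticDataset(
        exposure_table=exposure,
        outcome_table=outcome,
        mediator_table=mediator,
        ld_matrix=_ld_matrix(snp_ids, cfg),
        truth=truth,
    )
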