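"""Reading, validating and writing GWAS summary-statistic tables.

Summary statistics arrive as header-bearing TSV files (optionally
gzip-compressed) with one row per SNP.  Column names differ between
consortia (UK Biobank Neale-lab dialect, FinnGen, GIANT, ...), so the
reader takes an explicit column map rather than sniffing headers —
silent guessing is how alleles get corrupted.

Positions are 1-based.  Alleles are upper-cased on read; indel alleles
(length > 1) are accepted and are never treated as palindromic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("mrpipe")

#: canonical column order used internally and in written TSVs
STANDARD_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_VALID_BASES = set("ACGT")


class SumstatsError(Exception):
    """Base error for summary-statistic I/O and validation."""


class EmptyInputError(SumstatsError):
    """Raised when a table contains no valid rows."""


@dataclasses.dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association statistics in one GWAS.

    ``beta`` is the additive per-effect-allele effect on the trait
    scale: SD units for continuous traits, log-odds for binary ones.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G single-base pairs are strand-ambiguous."""
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclasses.dataclass
class GwasTable:
    """A validated GWAS summary-statistic table for one trait.

    Wraps a :class:`pandas.DataFrame` with the standard columns; rows
    are unique on ``snp_id``.
    """

    trait_name: str
    trait_unit: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in STANDARD_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"GwasTable missing columns: {missing}")
        if self.df.empty:
            logger.warning("GwasTable for %r is empty", self.trait_name)
        if self.df["snp_id"].duplicated().any():
            dupes = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].tolist()
            raise SumstatsError(f"duplicate snp_id values: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[SummaryStatRecord]:
        return [
            SummaryStatRecord(
                snp_id=str(r.snp_id),
                chrom=str(r.chrom),
                pos=int(r.pos),
                effect_allele=str(r.effect_allele),
                other_allele=str(r.other_allele),
                eaf=float(r.eaf) if pd.notna(r.eaf) else float("nan"),
                beta=float(r.beta),
                se=float(r.se),
                pval=float(r.pval),
                n=int(r.n),
            )
            for r in self.df.itertuples(index=False)
        ]

    def subset(self, snp_ids: Iterable[str]) -> "GwasTable":
        ids = set(snp_ids)
        sub = self.df[self.df["snp_id"].isin(ids)].reset_index(drop=True)
        return GwasTable(self.trait_name, self.trait_unit, sub)


@dataclasses.dataclass
class RunConfig:
    """Analysis thresholds and reproducibility settings.

    Defaults follow standard two-sample MR practice: genome-wide
    significance p < 5e-8, clumping at r^2 < 0.01 within a 10,000 kb
    window, palindromic SNPs resolved by allele frequency with an
    ambiguity band of (0.42, 0.58).
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000.0
    palindrome_policy: str = "eaf_infer"  # or "drop_all"
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58)
    seed: int = 0
    n_boot: int = 1000
    n_presso_sim: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 < self.clump_r2 < 1:
            raise ValueError("clump_r2 must be in (0, 1)")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be > 0")
        if self.palindrome_policy not in ("drop_all", "eaf_infer"):
            raise ValueError(f"unknown palindrome_policy {self.palindrome_policy!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "eaf_ambiguity_band" in data:
            data["eaf_ambiguity_band"] = tuple(data["eaf_ambiguity_band"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eaf_ambiguity_band"] = list(self.eaf_ambiguity_band)
        return d


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "",
    trait_unit: str = "",
) -> GwasTable:
    """Read a TSV of summary statistics into a validated :class:`GwasTable`.

    ``column_map`` maps standard field names (``snp_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
    ``se``, ``pval``, ``n``) to the file's column names.  With no map
    the file must already use the standard names.  ``eaf`` may be
    absent, in which case it is filled with NaN (palindrome inference
    then fails downstream, by design).

    Rows violating hard invariants (se <= 0, missing or identical
    alleles, eaf outside (0,1), pval outside (0,1]) are dropped and
    the kept/dropped split is logged.  A p-value inconsistent with
    |beta/se| under a two-sided normal test (by more than 10% relative
    tolerance) triggers a warning only: published files round p-values.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})

    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)

    required = [c for c in STANDARD_COLUMNS if c != "eaf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsError(f"{path}: missing mapped columns {missing}")
    if "eaf" not in df.columns:
        logger.warning("%s: no eaf column; palindromic SNPs cannot be frequency-aligned", path)
        df["eaf"] = np.nan

    df = df[STANDARD_COLUMNS].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    n_in = len(df)
    ok = (
        df["se"].gt(0)
        & df["beta"].notna()
        & df["pval"].gt(0)
        & df["pval"].le(1)
        & df["pos"].notna()
        & df["effect_allele"].str.fullmatch(r"[ACGT]+")
        & df["other_allele"].str.fullmatch(r"[ACGT]+")
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | (df["eaf"].gt(0) & df["eaf"].lt(1)))
    )
    dropped = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    logger.info("%s: %d rows read, %d kept, %d dropped", path, n_in, len(df), dropped)
    if df.empty:
        raise EmptyInputError(f"{path}: zero valid rows after filtering")
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(int)

    # soft consistency check: pval vs two-sided normal on beta/se
    z = (df["beta"] / df["se"]).abs()
    p_expect = 2.0 * stats.norm.sf(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(df["pval"].to_numpy() - p_expect) / np.maximum(p_expect, 1e-300)
    bad = int(((rel > 0.10) & (p_expect > 1e-300)).sum())
    if bad:
        logger.warning("%s: %d rows with p-value > 10%% off the normal beta/se test", path, bad)

    return GwasTable(trait_name or path.stem, trait_unit, df)


def write_sumstats(table: GwasTable, path: str | Path) -> None:
    """Write a GwasTable back to TSV with standard headers."""
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


#: column order of the results table (Table-2-style layout)
RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "cohort",
    "method",
    "n_snps",
    "beta",
    "se",
    "OR",
    "ci_low",
    "ci_high",
    "pval",
    "Q",
    "Q_pval",
    "egger_intercept_pval",
]


def write_results_table(results: Sequence[Mapping], path: str | Path) -> None:
    """Write MR estimates or mediation rows as a TSV.

    ``results`` is a sequence of dict-like rows; keys beyond the
    standard layout are appended as extra columns.  Floats keep >= 6
    significant digits so the table round-trips.
    """
    if not results:
        raise SumstatsError("refusing to write an empty results table")
    df = pd.DataFrame(list(results))
    lead = [c for c in RESULT_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df = df[lead + rest]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Timestamped logging to stderr and an optional file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)
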