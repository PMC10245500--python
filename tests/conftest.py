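import numpy as np
import pandas as pd
import pytest

from mrpipe.harmonization import HarmonizedInstrument
from mrpipe.sumstats_io import GwasTable, STANDARD_COLUMNS


def make_instruments(bx, by, sy, sx=None, ids=None):
    """Build harmonized instruments from plain arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    ids = ids or [f"rs{i + 1}" for i in range(len(bx))]
    return [
        HarmonizedInstrument(
            snp_id=i, beta_exposure=x, se_exposure=s_x,
            beta_outcome=y, se_outcome=s_y,
            eaf_exposure=0.3, eaf_outcome=0.3, action_taken="as_is",
        )
        for i, x, s_x, y, s_y in zip(ids, bx, sx, by, sy)
    ]


def make_table(rows, trait="trait", unit="SD"):
    """GwasTable from a list of dicts with standard-column defaults."""
    defaults = {
        "chrom": "1", "pos": 1000, "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.01, "pval": 1e-10, "n": 100000,
    }
    filled = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d["snp_id"] = f"rs{i + 1}"
        d["pos"] = 1000 + i * 50_000_000  # far apart unless overridden
        d.update(r)
        filled.append(d)
    df = pd.DataFrame(filled)[STANDARD_COLUMNS]
    return GwasTable(trait, unit, df)


@pytest.fixture
def rng():
    return np.random.default_rng(20230607)


@pytest.fixture
def ten_snp_instruments(rng):
    """A fixed 10-SNP instrument set with heterogeneous effects."""
    bx = rng.normal(0.05, 0.01, 10)
    sy = rng.uniform(0.005, 0.02, 10)
    by = 0.25 * bx + rng.normal(0, 1, 10) * sy
    return make_instruments(bx, by, sy)
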