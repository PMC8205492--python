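import numpy as np
import pandas as pd
import pytest
from scipy import stats

from postgwas.sumstats import SummaryStats


def make_sumstats(pos, beta, se, eaf=None, chrom="1", n=10000.0, info=1.0,
                  trait_id="t", trait_type="quantitative"):
    """Build a consistent SummaryStats table: p derived from beta/se."""
    pos = np.asarray(pos)
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    m = len(pos)
    eaf = np.full(m, 0.3) if eaf is None else np.asarray(eaf, dtype=float)
    p = np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    df = pd.DataFrame({
        "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), m).astype(str),
        "pos": pos, "ref": "A", "alt": "G", "eaf": eaf,
        "beta": beta, "se": se, "p": p,
        "n": np.broadcast_to(np.asarray(n, dtype=float), m),
        "info": np.broadcast_to(np.asarray(info, dtype=float), m),
    })
    return SummaryStats(trait_id, trait_type, df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_sumstats(rng):
    """200 null-ish variants with random but self-consistent statistics."""
    m = 200
    return make_sumstats(
        pos=np.sort(rng.choice(np.arange(1, 2_000_000), m, replace=False)),
        beta=rng.normal(0, 0.02, m),
        se=rng.uniform(0.01, 0.03, m),
        eaf=rng.uniform(0.01, 0.99, m),
        info=rng.uniform(0.3, 1.0, m),
    )
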