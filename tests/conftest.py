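import numpy as np
import pandas as pd
import pytest

from lipidprs.io import GenotypePanel, SummaryStats


def make_panel(dosages, chrom=None, pos=None, ea=None, nea=None,
               pos_spacing=10_000):
    """Build a GenotypePanel from an explicit (n x m) dosage array."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else 1000 + pos_spacing * np.arange(m),
        "id": [f"v{k}" for k in range(m)],
        "ea": ea if ea is not None else ["A"] * m,
        "nea": nea if nea is not None else ["G"] * m,
    })
    panel = GenotypePanel([f"s{i}" for i in range(n)], variants, dosages)
    panel.variants["eaf"] = panel.eaf()
    return panel


def make_sumstats(panel, beta, se=None, p=None, n=10_000):
    """Summary statistics aligned to a panel's variants."""
    m = panel.n_variants
    beta = np.asarray(beta, float)
    se = np.full(m, 0.01) if se is None else np.asarray(se, float)
    if p is None:
        from scipy import stats
        p = 2 * stats.norm.sf(np.abs(beta / se))
        p = np.clip(p, np.nextafter(0, 1), 1.0)
    df = panel.variants[["chrom", "pos", "id", "ea", "nea"]].copy()
    df["beta"], df["se"], df["p"], df["n"] = beta, se, p, n
    return SummaryStats(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    from lipidprs.sim import SimulationConfig
    return SimulationConfig(n_ref=300, n_gwas=3000, m_variants=200,
                            block_size=10, ld_decay=0.6, p_causal=0.05,
                            h2=0.5, seed=7)
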