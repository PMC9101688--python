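import numpy as np
import pandas as pd
import pytest

from mrpipe.io import CANONICAL_COLUMNS, GwasTable


def make_instruments(gamma, se_gamma, big_gamma, se_big_gamma, eaf=None, snps=None):
    """Build a harmonized instrument frame from plain arrays."""
    gamma = np.asarray(gamma, float)
    L = len(gamma)
    df = pd.DataFrame(
        {
            "SNP": snps if snps is not None else [f"rs{i:04d}" for i in range(L)],
            "effect_allele": "A",
            "other_allele": "G",
            "gamma_hat": gamma,
            "se_gamma": np.broadcast_to(np.asarray(se_gamma, float), (L,)).copy(),
            "big_gamma_hat": np.asarray(big_gamma, float),
            "se_big_gamma": np.broadcast_to(
                np.asarray(se_big_gamma, float), (L,)
            ).copy(),
            "eaf_exposure": 0.3 if eaf is None else np.asarray(eaf, float),
            "eaf_outcome": 0.3 if eaf is None else np.asarray(eaf, float),
        }
    )
    return df


def make_gwas_table(rows, trait_label="trait"):
    """GwasTable from a list of dicts with canonical fields."""
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return GwasTable(df[CANONICAL_COLUMNS].copy(), trait_label=trait_label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def homogeneous_instruments(rng):
    """50 valid instruments, true slope 0.354, modest noise."""
    L = 50
    g = rng.uniform(0.05, 0.2, L)
    sg = np.full(L, 0.005)
    sG = np.full(L, 0.01)
    G = 0.354 * g + sG * rng.standard_normal(L)
    return make_instruments(g, sg, G, sG)
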