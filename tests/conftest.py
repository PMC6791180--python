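import numpy as np
import pandas as pd
import pytest

from castemeth import synthetic_data as sd


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study shared by read-only tests."""
    cfg = sd.SimConfig(
        n_sites=2000, n_genes=100, n_dm_sites=40, n_dm_genes=8,
        dm_effect=0.30, colony_sd=0.5, seed=7,
    )
    return sd.simulate_wgbs(cfg)


@pytest.fixture(scope="session")
def dm_sim():
    """The differential-methylation benchmark configuration."""
    cfg = sd.SimConfig(
        n_sites=5000, n_dm_sites=100, n_dm_genes=20, dm_effect=0.30,
        colony_sd=0.5, seed=1,
    )
    return sd.simulate_wgbs(cfg)


def make_counts(chrom, positions, n_meth, n_total, strand="+"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "strand": strand,
            "n_meth": np.asarray(n_meth, dtype=np.int64),
            "n_total": np.asarray(n_total, dtype=np.int64),
        }
    )
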