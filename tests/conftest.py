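import numpy as np
import pandas as pd
import pytest

from finsynt import SimConfig, simgenome as sg


@pytest.fixture(scope="session")
def small_dataset():
    """One moderate simulated dataset shared by read-only tests."""
    cfg = SimConfig(seed=4, n_clg=3, genes_per_clg=200, tad_size_mean=400_000)
    return sg.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def tss_table(genes: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": genes["chrom"],
        "pos": np.where(genes["strand"] == "+", genes["start"], genes["end"]),
        "gene_id": genes["gene_id"],
    })
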