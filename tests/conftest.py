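import numpy as np
import pandas as pd
import pytest

from haplopop import (MISSING, GenotypeDataset, MatTable, SitesTable,
                      paper_scale_config, simulate)


@pytest.fixture
def tiny_data() -> GenotypeDataset:
    """Four samples, two populations in two regions, two loci, one missing."""
    calls = np.array([
        [100, 203],
        [100, 205],
        [102, MISSING],
        [102, 205],
    ])
    return GenotypeDataset(
        sample_ids=["a1", "a2", "b1", "b2"],
        loci=["L1", "L2"],
        calls=calls,
        pop_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        region_of={"A": "west", "B": "east"},
    )


@pytest.fixture
def tiny_sites() -> SitesTable:
    return SitesTable(pd.DataFrame({
        "population": ["A", "B"],
        "region": ["west", "east"],
        "latitude": [40.0, 41.0],
        "longitude": [-5.0, 3.0],
    }))


@pytest.fixture(scope="session")
def paper_sim():
    """One paper-scale synthetic dataset shared across tests."""
    return simulate(paper_scale_config(seed=7))


def make_dataset(calls, pops, regions=None, loci=None):
    """Convenience constructor for hand-built genotype tables."""
    calls = np.asarray(calls, dtype=np.int64)
    n, l = calls.shape
    ids = [f"s{i}" for i in range(n)]
    loci = loci or [f"L{j + 1}" for j in range(l)]
    pop_of = dict(zip(ids, pops))
    if regions is None:
        regions = {p: "all" for p in set(pops)}
    return GenotypeDataset(ids, loci, calls, pop_of, regions)
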