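import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from chipdyn.genome import BinnedTrack, GenomeLayout


@pytest.fixture
def tiny_layout():
    """Two small chromosomes at 25-bp bins."""
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000}, bin_width=25)


@pytest.fixture
def constant_track(tiny_layout):
    data = {c: np.ones(tiny_layout.n_bins(c)) for c in tiny_layout.chroms}
    return BinnedTrack(tiny_layout, data, "log2fc")


@pytest.fixture
def toy_genes(tiny_layout):
    return pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "chrom": ["chr1", "chr1", "chr2"],
        "tss": [2000, 6000, 3000],
        "strand": ["+", "-", "+"],
        "gene_end": [3200, 4800, 4200],
    })


def rng_track(layout, seed, kind="counts", low=0, high=100):
    rng = np.random.default_rng(seed)
    data = {c: rng.integers(low, high, layout.n_bins(c)).astype(float)
            for c in layout.chroms}
    return BinnedTrack(layout, data, kind)
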