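import numpy as np
import pytest

from niptcall import RunConfig, default_genome_bins, make_genome_bins
from niptcall.pipeline import build_panel_from_sims


@pytest.fixture(scope="session")
def bins():
    """Bundled hg19-scale 1-Mb bin model."""
    return default_genome_bins()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def toy_bins():
    """Small autosome-only genome for fast normalization tests."""
    rng = np.random.default_rng(77)
    lengths = {"1": 150_000_000, "2": 120_000_000, "3": 90_000_000}
    n = sum(-(-v // 10**6) for v in lengths.values())
    gc = np.clip(rng.normal(0.42, 0.05, n), 0.25, 0.65)
    return make_genome_bins(lengths, 1_000_000, gc=gc)


@pytest.fixture(scope="session")
def panel(bins):
    """Euploid reference panel under screening conditions (~0.1x depth)."""
    return build_panel_from_sims(bins, seed=20250901)
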