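import numpy as np
import pytest

import copulageo as cg


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset on a 2x2 region grid (seeded)."""
    return cg.simulate_dataset(cg.SyntheticConfig(n=1200, grid=(2, 2), seed=42))


@pytest.fixture(scope="session")
def fe_fit(small_dataset):
    """Fixed-effects-only gumbel fit of the small dataset."""
    spec = cg.ModelSpec.fixed_effects_only()
    return cg.fit_model(spec, small_dataset.records)


@pytest.fixture(scope="session")
def geo_fit():
    """Geo-additive fit of a small dataset (session-cached: it is the
    workhorse fixture for inference/prediction contracts)."""
    ds = cg.simulate_dataset(cg.SyntheticConfig(n=2000, grid=(3, 3), seed=7))
    spec = cg.ModelSpec.geoadditive()
    fit = cg.fit_model(spec, ds.records, graph=ds.graph)
    return ds, fit


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
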