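import numpy as np
import pytest
from hypothesis import settings

import ppidiff as pp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


_DESIGN_CACHE = {}


def cached_dpc_design(seed, effect_size=None):
    """Dataset plus its DPC design matrix, memoized across tests."""
    key = (seed, effect_size)
    if key not in _DESIGN_CACHE:
        kw = {} if effect_size is None else {"effect_size": effect_size}
        ds = pp.generate_dataset(pp.SyntheticConfig(seed=seed, **kw))
        X, y = build_dpc_design(ds)
        _DESIGN_CACHE[key] = (ds, X, y)
    return _DESIGN_CACHE[key]


def build_dpc_design(dataset, mode="absolute"):
    """Full small pipeline: DPC features -> normalize -> pair differences."""
    feats = pp.compute_matrix(
        dataset.proteins.records, pp.DescriptorConfig(families=("DPC",))
    )
    params = pp.fit_normalization(feats)
    normalized = pp.apply_normalization(feats, params)
    design = pp.build_design_matrix(list(dataset.pairs), normalized, mode=mode)
    return pp.split_design_matrix(design)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the default study conditions (seed 0)."""
    return pp.generate_dataset(pp.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_design(default_dataset):
    """DPC design matrix (X DataFrame, y) for the default dataset."""
    return build_dpc_design(default_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
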