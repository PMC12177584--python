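import numpy as np
import pytest

from flimdose import (
    GeneratorConfig,
    build_feature_table,
    conform_lengths,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_ds():
    """Full default design (6 conc x 5 exp x 10 cells), conformed, with truth."""
    ds, truth = generate_dataset(GeneratorConfig(seed=1))
    return conform_lengths(ds), truth


@pytest.fixture(scope="session")
def default_table(default_ds):
    ds, _ = default_ds
    return build_feature_table(ds, target_name="dosage", include_interactions=True)


@pytest.fixture(scope="session")
def small_ds():
    """Reduced design (2 cells/condition, 500-point curves) for fast tests."""
    cfg = GeneratorConfig(cells_per_condition=2, n_points=500, seed=7,
                          length_jitter=False)
    ds, truth = generate_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def small_table(small_ds):
    ds, _ = small_ds
    return build_feature_table(ds, target_name="dosage", include_interactions=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
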