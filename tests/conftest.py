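import numpy as np
import pytest

import crossband as cb


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic dataset shared by read-only tests."""
    cfg = cb.scaled_config(n_cortical=6, n_subcortical=2, n_nongray=2,
                           n_visual=3, n_subjects=4, run_length_tr=400, seed=3)
    dataset, truth = cb.generate_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_prepared(small_sim):
    _, dataset, _ = small_sim
    return cb.prepare_dataset(dataset)


@pytest.fixture(scope="session")
def small_design(small_prepared):
    return cb.assemble_design(small_prepared, None, "alpha")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
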