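import numpy as np
import pytest

import dynfc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small signal-level cohort shared across tests (10 subjects, 8 components)."""
    spec = dynfc.SyntheticSpec(
        n_patients=5, n_controls=5, n_components=8, n_timepoints=170, seed=3
    )
    tsset, truth = dynfc.generate_cohort(spec)
    return spec, tsset, truth


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    """Feature table (hurst + variance + static) for the tiny cohort."""
    _, tsset, _ = tiny_cohort
    clean = dynfc.postprocess_cohort(tsset)
    tensor = dynfc.dynamic_fc_tensor(clean)
    static = dynfc.static_fc(clean)
    return dynfc.build_feature_table(tensor, static=static)
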