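import numpy as np
import pytest

from sfcoupling import (
    SyntheticConfig,
    generate_cohort,
    build_connectome,
    structure_function_coupling,
)


@pytest.fixture(scope="session")
def demo_cohort():
    """A small cohort with a planted two-ROI circuit, shared across tests."""
    cfg = SyntheticConfig(
        n_subjects=40,
        n_rois=14,
        n_timepoints=150,
        signal_rois=(2, 5),
        effect_size=0.9,
        seed=11,
    )
    records = generate_cohort(cfg)
    cc = build_connectome(records)
    return cfg, records, cc


@pytest.fixture(scope="session")
def demo_coupling(demo_cohort):
    _, _, cc = demo_cohort
    return structure_function_coupling(cc)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
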