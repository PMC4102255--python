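import numpy as np
import pytest

from ewasmeta.synthio import SimConfig, simulate_beta, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """A small but fully featured cohort used across module tests."""
    return SimConfig(
        n_cases_per_batch=(15, 18, 16),
        n_controls_per_batch=(17, 20, 18),
        n_probes_panel_small=120,
        n_probes_panel_large=160,
        n_overlap=100,
        n_true_risk_probes=5,
        n_celltype_probes=10,
        n_true_survival_probes=3,
        n_crossreactive_probes=8,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    sheet, truth = simulate_cohort(tiny_config)
    beta = simulate_beta(sheet, truth, tiny_config)
    return sheet, truth, beta


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
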