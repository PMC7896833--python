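import numpy as np
import pytest

from wsdlprog import CohortConfig, NetworkConfig, simulate_cohort
from wsdlprog.pnu_classifier import PnuConfig
from wsdlprog.wsdl_pipeline import PipelineConfig


@pytest.fixture(scope="session")
def small_cohort_config():
    """Desk-scale cohort: 20 labeled (14 train / 6 test), 12 unlabeled."""
    return CohortConfig(
        n_labeled=20,
        n_unlabeled=12,
        train_fraction=14 / 20,
        relapse_prevalence=0.3,
        effect_size=1.5,
        grid_shape=(36, 36, 36),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return simulate_cohort(small_cohort_config)


def fast_network_config(**overrides) -> NetworkConfig:
    """16^3-input network small enough for second-scale training in tests."""
    kwargs = dict(
        input_voxels=16,
        stage_widths=(4, 8, 16, 128),
        blocks_per_stage=1,
        batch_size=8,
        max_epochs=20,
        early_stop_patience=6,
        learning_rate=3e-3,
        seed=0,
    )
    kwargs.update(overrides)
    return NetworkConfig(**kwargs)


def fast_pipeline_config(**overrides) -> PipelineConfig:
    net = overrides.pop("network", None) or fast_network_config(
        seed=overrides.pop("seed", 0)
    )
    kwargs = dict(
        side_mm=96.0,
        out_voxels=16,
        network=net,
        pnu=PnuConfig(l2_penalty=1e-2, cv_folds=3, seed=net.seed),
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(1234)
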