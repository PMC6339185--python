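import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from haradapt.adapt import TrainConfig
from haradapt.model import NetConfig
from haradapt.sensordata import (
    SimulatorConfig,
    make_domain_split,
    simulate_population,
    zscore_normalize,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TINY_SIM = dict(
    n_subjects=2, n_activities=3, windows_per_class=20, T=32, C=3,
    base_freqs_hz=[0.8, 1.6, 2.4], n_harmonics=2, seed=7,
)


@pytest.fixture(scope="session")
def tiny_population():
    """Two subjects, three activities, 60 windows each — fast shared input."""
    return simulate_population(SimulatorConfig(**TINY_SIM))


@pytest.fixture(scope="session")
def tiny_split(tiny_population):
    src = zscore_normalize(tiny_population[0], tiny_population[0])
    tgt = zscore_normalize(tiny_population[1], tiny_population[0])
    return make_domain_split(src, tgt, 2.0 / 3.0, seed=0)


@pytest.fixture
def tiny_net():
    return NetConfig(n_classes=3, in_shape=(32, 3), n_conv_kernels=8, fc_units=16)


def tiny_train_config(method="only_source", **kw):
    kw.setdefault("iterations", 20)
    kw.setdefault("batch_size", 16)
    return TrainConfig(method=method, **kw)
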