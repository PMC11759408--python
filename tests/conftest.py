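import numpy as np
import pytest

from synconv.config import NetworkConfig, builtin_config


@pytest.fixture(scope="session")
def toy_config() -> NetworkConfig:
    """Small dendrite with unit synapse spacing for hand-checkable motifs."""
    return NetworkConfig(
        name="toy", p=0.5, T_pre=60, R=0.1, D=1.0,
        Z=4.0, S=2.0, delta=2.0, L=30.0, sigma=1.0, N=2, M=3, T_post=100,
    )


@pytest.fixture(scope="session")
def piriform_config() -> NetworkConfig:
    """Olfactory-bulb-to-piriform worked example: pN = 1.28 on a 2000 um arbor."""
    return NetworkConfig(
        name="piriform", p=0.0064, T_pre=1_000_000, R=0.0, D=1.0,
        Z=50.0, S=10.0, delta=5.0, L=2000.0, N=200, M=4,
    )


@pytest.fixture(scope="session")
def hippo_cicr_seq() -> NetworkConfig:
    return builtin_config("hippo-CICR", N=1000)


@pytest.fixture(scope="session")
def tuned_sequence_params(hippo_cicr_seq):
    """Session-cached tuned recurrence parameters (M=4, target 0.8)."""
    from synconv.activation import tune_sequence_params

    return tune_sequence_params(hippo_cicr_seq, 0.8, M=4)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
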