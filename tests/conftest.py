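import numpy as np
import pytest

from sacuq import (
    ArchitectureConfig,
    ClassGeneratorConfig,
    TrainConfig,
    build_model,
    generate_dataset,
    train,
)


def small_generator_config(size_lo=8, size_hi=15, **kwargs) -> ClassGeneratorConfig:
    """Generator config with small registers for fast tests."""
    return ClassGeneratorConfig(
        register_size_mean_sd={
            c: ((size_lo + size_hi) / 2.0, float(size_hi - size_lo))
            for c in ("C", "P", "S")
        },
        register_size_bounds={c: (size_lo, size_hi) for c in ("C", "P", "S")},
        **kwargs,
    )


@pytest.fixture(scope="session")
def tiny_arch() -> ArchitectureConfig:
    return ArchitectureConfig(n_filters=8, lstm_units=12)


@pytest.fixture(scope="session")
def small_dataset():
    """18 registers (6 per class), 8-15 saccades each, default waveforms."""
    return generate_dataset((6, 6, 6), small_generator_config(), seed=11)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_arch, small_dataset):
    """A small CNN-LSTM trained briefly on the small synthetic dataset."""
    model = build_model(tiny_arch)
    train(model, small_dataset, TrainConfig(epochs=5, batch_size=32, seed=3))
    return model


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
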