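import numpy as np
import pytest

from flydec import ModelConfig, build_model, encode, train_task


@pytest.fixture
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trained_model_factory():
    """Build-and-train cache: conditioning runs are the expensive part of
    the suite, so identical (seed, ci) trainings are shared across tests."""
    cache: dict = {}

    def factory(seed: int = 0, ci: float = 1.0, shapes=("upright", "inverted")):
        key = (seed, ci, shapes)
        if key not in cache:
            model = build_model(seed=seed)
            safe = encode("green", shapes[0], ci)
            punished = encode("blue", shapes[1], ci)
            train_task(model, safe, punished, epochs=1)
            cache[key] = model
        return cache[key].copy()

    return factory
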