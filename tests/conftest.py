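import numpy as np
import pytest

from cgmunet import NetworkConfig, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Smallest practical network (depth 2) used by training tests."""
    return NetworkConfig(depth=2, stage_widths=(8, 16),
                         bottleneck_gate_width=16, output_width=8,
                         dropout_rate=0.0)


@pytest.fixture(scope="session")
def toy_samples():
    """Eight 64x64 synthetic lesion samples (the overfit study condition)."""
    cfg = SyntheticConfig(n_images=8, image_size=(64, 64), seed=7)
    return generate_dataset(cfg)


def numerical_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar-valued f at x (float64)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g
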