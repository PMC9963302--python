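import numpy as np
import pytest

from synquant.synthetic import StackSpec, SynapseSpec, render_stack, render_synapse


@pytest.fixture()
def quiet_synapse_spec() -> SynapseSpec:
    """Noise-free synapse spec used by several modules."""
    return SynapseSpec(seed=42)


@pytest.fixture()
def synapse_image(quiet_synapse_spec):
    return render_synapse(quiet_synapse_spec)


@pytest.fixture()
def small_stack_spec() -> StackSpec:
    """Small noise-free stack for fast 3D tests."""
    return StackSpec(
        volume_size_px=(24, 64, 64),
        cell_semiaxes_um=(3.0, 3.0, 2.0),
        poisson_noise=False,
        gaussian_noise_sd=0.0,
        seed=7,
    )


@pytest.fixture()
def small_stack(small_stack_spec):
    return render_stack(small_stack_spec)


def pearson_two_pass(a: np.ndarray, b: np.ndarray) -> float:
    """Independent two-pass Pearson correlation used as an oracle."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sum((x - ma) ** 2 for x in a) ** 0.5
    db = sum((y - mb) ** 2 for y in b) ** 0.5
    return num / (da * db)
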