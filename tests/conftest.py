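import numpy as np
import pytest

from mechlearn import datasets
from mechlearn.datasets import DensityDataset


@pytest.fixture
def toy_dataset():
    """A deterministic 5 x 3 x 2 raw-unit dataset."""
    positions = np.array([25.0, 75.0, 125.0, 175.0, 225.0])
    times = np.array([0.0, 12.0, 24.0])
    rng = np.random.default_rng(42)
    densities = 1e-3 * (1.0 + 0.2 * rng.standard_normal((5, 3, 2)))
    return DensityDataset(positions, times, densities, units_state="raw")


@pytest.fixture
def smooth_dataset():
    """Noise-free rescaled data from a smooth analytic field u = f(x, t).

    f(x, t) = 300 + 200 sin(pi xi) (1 + 0.3 tau) on the unit square; the
    analytic derivatives are attached for oracle comparisons.
    """
    n, m = 12, 8
    positions = np.linspace(0.0, 1.8, n)  # mm
    times = np.linspace(0.0, 2.0, m)  # d
    xi = (positions - positions[0]) / (positions[-1] - positions[0])
    tau = (times - times[0]) / (times[-1] - times[0])
    XI, TAU = np.meshgrid(xi, tau, indexing="ij")
    field = 300.0 + 200.0 * np.sin(np.pi * XI) * (1.0 + 0.3 * TAU)
    data = DensityDataset(
        positions, times, field[:, :, None], units_state="rescaled"
    )
    return data, field
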