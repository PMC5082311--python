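import numpy as np
import pytest

from pathgc import TimeSeriesPanel


@pytest.fixture
def make_white_panel():
    """Factory for i.i.d. Gaussian panels."""

    def _make(n_timepoints=1000, n_channels=2, seed=0, sampling_interval_s=None):
        rng = np.random.default_rng(seed)
        return TimeSeriesPanel(
            rng.standard_normal((n_timepoints, n_channels)),
            sampling_interval_s=sampling_interval_s,
        )

    return _make


@pytest.fixture
def small_panel():
    """A tiny fixed 6-row, 2-channel panel for exact-arithmetic checks."""
    values = np.array(
        [
            [0.5, -1.2],
            [1.1, 0.3],
            [-0.7, 0.8],
            [0.2, -0.5],
            [-1.3, 1.0],
            [0.9, -0.1],
        ]
    )
    return TimeSeriesPanel(values, ["x", "y"])
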