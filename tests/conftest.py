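import numpy as np
import pytest

from hitfinder.synthetic import SimulationParams


@pytest.fixture
def clean_params():
    """Artefact-free small-frame conditions: Poisson background only."""
    return SimulationParams(
        frame_height=64,
        frame_width=64,
        background_rate=0.0,
        hot_pixel_fraction=0.0,
        fixed_pattern_amplitude=0.0,
        n_peaks_range=(3, 3),
        peak_amplitude_range=(100.0, 300.0),
        min_peak_separation=8.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
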