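import numpy as np
import pytest

from plusend import FilamentTrack, SimConfig


@pytest.fixture
def linear_track() -> FilamentTrack:
    """Noise-free track growing 0.1 µm per 5 s frame over 0..20 s."""
    times = np.arange(0.0, 25.0, 5.0)
    return FilamentTrack(filament_id=0, fov_id=0, times=times, lengths=0.1 * times)


def make_track(lengths, dt=5.0, filament_id=0, fov_id=0) -> FilamentTrack:
    lengths = np.asarray(lengths, dtype=float)
    times = np.arange(lengths.size) * dt
    return FilamentTrack(
        filament_id=filament_id, fov_id=fov_id, times=times, lengths=lengths
    )


@pytest.fixture
def quiet_config() -> SimConfig:
    """No noise, no state transitions: pure free-end growth."""
    return SimConfig(length_noise_sd=0.0, transition_rates={}, movie_duration=200.0)
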