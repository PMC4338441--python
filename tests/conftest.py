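import numpy as np
import pytest

from kar3team.synthetic_data import MotionPreset, MovieSpec, generate_tracks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def directed_tracks():
    """Small wild-type-like directed population (fast to generate)."""
    preset = MotionPreset("wt_small", "directed", velocity_mean=77.0,
                          velocity_sd=23.0, run_length_mean=5200.0)
    return generate_tracks(preset, 60, 0.2, seed=11)


@pytest.fixture
def movie_layout():
    """Standard small rendering geometry used across tracking tests."""
    return MovieSpec(
        shape=(48, 128), n_frames=15, frame_interval_s=3.0,
        background=100.0, read_noise_sd=2.0,
        axis_start=(24.0, 4.0), axis_end=(24.0, 124.0),
    )


def staggered_tracks(n=10, spacing_nm=2000.0, seed=1, intensity=1200.0,
                     duration=42.0, velocity_sd=5.0):
    """Directed tracks offset along the axis so spots stay resolvable."""
    preset = MotionPreset("track_test", "directed", velocity_mean=77.0,
                          velocity_sd=velocity_sd, run_length_mean=50000.0,
                          localization_sd=10.0)
    tracks, truth = generate_tracks(preset, n, 3.0, seed, duration=duration,
                                    intensity=intensity)
    for i, t in enumerate(tracks):
        t.position_nm = t.position_nm + i * spacing_nm
    return tracks, truth
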