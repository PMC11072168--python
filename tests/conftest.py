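import numpy as np
import pytest

from sweptsa.acquisition import P4_2V, TransmitEvent
from sweptsa.simulate import ScattererField, depth_time_window, simulate_frame
from sweptsa.studies import _plane_frames, _track_images, _tracking_field


@pytest.fixture(scope="session")
def spec():
    return P4_2V


@pytest.fixture(scope="session")
def small_speckle_field(spec):
    """Compact speckle slab shared by estimation tests (one realization)."""
    return _tracking_field((-13e-3, 13.5e-3), seed=42, spec=spec)


@pytest.fixture(scope="session")
def tracking_pair(spec, small_speckle_field):
    """Plane-wave frames at poses 0 and 0.10 mm plus their beamformed images."""
    poses = [0.0, 0.10e-3]
    frames = _plane_frames(small_speckle_field, spec, poses)
    images = _track_images(frames, search=2.5e-3)
    return frames, images, poses


@pytest.fixture(scope="session")
def single_point_frame(spec):
    """One on-axis scatterer at 10 mm depth, 0° plane transmit."""
    field = ScattererField(
        positions=np.array([[0.0, 0.0, 10e-3]]),
        amplitudes=np.array([1.0]),
        extents=np.array([[-1e-3, 1e-3], [0.0, 0.0], [9e-3, 11e-3]]),
    )
    t0, n = depth_time_window((8e-3, 12e-3), spec)
    return simulate_frame(field, spec, TransmitEvent("plane"), fs=20e6, t0=t0, n_samples=n)
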