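import numpy as np
import pytest
from hypothesis import settings

from gazeroi.io_formats import ROI_LABELS, RoiTrack, ScreenGeometry
from gazeroi.synthetic_data import default_motion_spec, generate_roi_track

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    """The study's screen: 1920x1080 at 25 fps, 47.5 x 27.8 deg."""
    return ScreenGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """A reduced frame with the same deg-per-px aspect, for mask-heavy tests."""
    return ScreenGeometry(width_px=192, height_px=108, width_deg=47.5, height_deg=27.8)


@pytest.fixture(scope="session")
def static_track(geometry):
    """Full-resolution static scene (masks shared across all frames)."""
    track, spec = generate_roi_track(
        seed=7,
        motion_spec=default_motion_spec(geometry, moving=False),
        window_ms=12_000.0,
    )
    return track, spec


@pytest.fixture(scope="session")
def moving_track(geometry):
    """Full-resolution moving scene over a short 2-s window."""
    track, spec = generate_roi_track(seed=11, window_ms=2_000.0)
    return track, spec


def make_tiny_track(masks_by_label, width=20, height=20, n_frames=1, fps=25.0):
    """Single-scene track on a tiny frame, for hand-computable assignment."""
    geom = ScreenGeometry(
        width_px=width, height_px=height, width_deg=47.5, height_deg=27.8, frame_rate_hz=fps
    )
    window = (0.0, n_frames * 1000.0 / fps)
    frame = {}
    for label in ROI_LABELS:
        m = masks_by_label.get(label)
        frame[label] = np.zeros((height, width), dtype=bool) if m is None else np.asarray(m, bool)
    frames = {i: frame for i in range(n_frames)}
    return RoiTrack.from_masks(geom, window, frames)
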