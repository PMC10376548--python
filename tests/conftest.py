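import numpy as np
import pytest

from mechanovibe import schedule as sched
from mechanovibe import synth


@pytest.fixture(scope="session")
def rp_schedule_short():
    """A 10 s Regular Pulse schedule (1000 ms pulse / 1000 ms interval)."""
    return sched.generate_rp_schedule(10.0, 1000, 1000)


@pytest.fixture(scope="session")
def rp_trace_short(rp_schedule_short):
    """Noise-free accelerometer emulation of the short RP schedule."""
    return synth.make_accel_trace(
        rp_schedule_short, amplitude_g=2.39, carrier_hz=50.0, sample_rate=3200.0
    )


@pytest.fixture(scope="session")
def filament_scene():
    """A deterministic 20-filament scene with ground truth."""
    spec = synth.random_filament_scene(n_filaments=20, seed=0)
    return synth.make_filament_image(spec)


@pytest.fixture(scope="session")
def vortex_video():
    """Two-vortex particle video with ground-truth tracks and analytic field."""
    spec = synth.FlowSceneSpec(
        n_particles=150, n_frames=60, seed=2, stream_amplitude=2e-6
    )
    return (*synth.make_particle_video(spec), spec)


def match_filaments(truth, filaments, image_height):
    """Pair each planted filament with the nearest recovered one.

    Returns a list of (truth_row, filament) pairs keyed on skeleton
    centroid distance to the planted center.
    """
    pairs = []
    for _, row in truth.iterrows():
        best = None
        for f in filaments:
            pts = np.asarray(f.skeleton_path, dtype=float)
            cx = pts[:, 1].mean()
            cy = (image_height - 1) - pts[:, 0].mean()
            d = np.hypot(cx - row.cx_px, cy - row.cy_px)
            if best is None or d < best[0]:
                best = (d, f)
        if best is not None:
            pairs.append((row, best[1], best[0]))
    return pairs
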