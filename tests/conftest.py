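import dataclasses

import numpy as np
import pytest

import spherotox as st
from spherotox.scene_sim import density_for_count


@pytest.fixture(scope="session")
def small_scene():
    """One gel-seeded kill-on-contact scene shared by read-only tests."""
    base = st.SceneConfig(n_frames=30, kill_rate=0.02, infiltration_rate=0.05)
    cfg = dataclasses.replace(
        base, rng_seed=11, effector_density=density_for_count(base, 200)
    )
    truth = st.simulate_agents(cfg)
    stack = st.render_frames(truth, cfg)
    return cfg, truth, stack


@pytest.fixture(scope="session")
def small_tracks(small_scene):
    cfg, truth, stack = small_scene
    params = st.SegmentationParams(pixel_size=cfg.pixel_size)
    bf = stack.channel("BF")
    labels = [st.segment_spheroids(bf[i], params) for i in range(stack.n_frames)]
    tracks = st.track_labels(labels, 50.0, cfg.pixel_size)
    return [t for t in tracks if len(t.entries) == stack.n_frames]


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
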