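import numpy as np
import pytest

import fishgait as fg
from fishgait import kinematics as K

# realistic rendering conditions used throughout: backlit arena with mild
# sensor noise and illumination gradient (histogram-based thresholding is
# only well posed with realistic background statistics)
RENDER = dict(antialias=True, noise_sigma=2.0, illumination=6.0)


@pytest.fixture(scope="session")
def adult_params():
    return fg.TrackerParams.for_size_class("large_adult")


@pytest.fixture(scope="session")
def finned_shape():
    return fg.FishShapeSpec(fins_enabled=True)


@pytest.fixture(scope="session")
def plain_shape():
    return fg.FishShapeSpec(fins_enabled=False)


def render(shape, heading=0.3, bend=0.0, onset=0.6, seed=1, canvas=(400, 300)):
    pose = fg.PoseSpec(
        position=(canvas[0] / 2, canvas[1] / 2),
        heading=heading,
        bend_amplitude=bend,
        bend_onset=onset,
    )
    return fg.render_fish_mask(
        shape, pose, canvas, rng=np.random.default_rng(seed), **RENDER
    )


@pytest.fixture(scope="session")
def short_video(finned_shape):
    """3 s, 100 fps rendered swim video with ground truth (session-cached)."""
    script = fg.random_swim_script(11, duration=3.0)
    frames, truth = fg.render_swim_video(finned_shape, script)
    return frames, truth, script


def series_from_sim(sim, mm_per_px=1.0):
    """Wrap simulated traces as a KinematicSeries (perfect measurement)."""
    return K.KinematicSeries(
        t=sim.t,
        v=sim.v,
        v_raw=sim.v,
        theta=sim.theta,
        alpha=sim.alpha,
        k=sim.k,
        fps=sim.fps,
        mm_per_px=mm_per_px,
        quality=np.ones(len(sim.t), dtype=bool),
    )
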