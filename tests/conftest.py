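import logging

import numpy as np
import pytest

from astrofiu import SimulationConfig, VideoStack, generate_scene, render_video

logging.getLogger("astrofiu").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_scene():
    """A 64x64 movie with 6 units at 10 dB: comfortable SNR, all stages work."""
    cfg = SimulationConfig(height=64, width=64, n_fius=6, snr_db=10.0,
                           area_range=(30, 200), seed=1)
    scene = generate_scene(cfg)
    return scene, render_video(scene)


@pytest.fixture(scope="session")
def low_snr_scene():
    cfg = SimulationConfig(height=64, width=64, n_fius=6, snr_db=5.0,
                           area_range=(30, 200), seed=2)
    scene = generate_scene(cfg)
    return scene, render_video(scene)


@pytest.fixture(scope="session")
def noise_stack():
    """Pure i.i.d. Gaussian noise, no structure at all."""
    rng = np.random.default_rng(1234)
    return VideoStack(rng.standard_normal((100, 64, 64)))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
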