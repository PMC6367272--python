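"""Shared fixtures: textured test images and a tracked default scene."""

import numpy as np
import pytest
import scipy.ndimage as ndi

import audiencemotion as am


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_speckle(shape=(128, 128), seed=0, smooth=1.5):
    """A smooth random texture suitable for optical flow."""
    r = np.random.default_rng(seed)
    img = r.uniform(0.0, 255.0, size=shape)
    return ndi.gaussian_filter(img, smooth)


@pytest.fixture(scope="session")
def speckle():
    return make_speckle()


@pytest.fixture(scope="session")
def default_scene():
    """The generator's default scene (256x256, 30 fps, 30 s) with tracks."""
    cfg = am.SceneConfig(seed=3)
    seq, truth = am.generate_scene(cfg)
    thr = am.default_threshold(seq.frames[0])
    detections = [am.detect_blobs(f, thr) for f in seq.frames]
    tracks = am.link_tracks(detections, cfg.envelopes)
    return cfg, seq, truth, detections, tracks
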