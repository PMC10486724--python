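import numpy as np
import pytest

import afmtopo as at


@pytest.fixture(scope="session")
def control_scene():
    """One control-preset scene with its ground truth, shared read-only."""
    params = at.scene_from_preset("control", seed=11)
    hmap, truth = at.make_scene(params)
    return params, hmap, truth


@pytest.fixture(scope="session")
def spread_scene():
    params = at.scene_from_preset("spread_segmented", seed=7)
    hmap, truth = at.make_scene(params)
    return params, hmap, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def centered_cosine(n, dx, period, amplitude, phase=0.0):
    """Cosine sampled at pixel centres; an integer number of periods over the
    window then has exactly zero linear trend, so its one-sided spectrum is
    A^2 in one bin to machine precision."""
    x = (np.arange(n) + 0.5) * dx
    return amplitude * np.cos(2 * np.pi * x / period + phase)
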