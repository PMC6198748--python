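import numpy as np
import pytest

from fibrilmech import mechanics, synth


@pytest.fixture(scope="session")
def default_truth() -> synth.FibrilGroundTruth:
    """Study-condition fibril: 100 nm radius, 50 um segment, 67 nm D-band,
    rupture at 20% strain with a linear 500 MPa response."""
    return synth.FibrilGroundTruth()


@pytest.fixture(scope="session")
def noiseless_pull(default_truth):
    """Frictionless, noiseless pull experiment plus its analysis output."""
    exp = synth.make_pull_experiment(default_truth, friction_level_un=0.0,
                                     friction_sd_un=0.0, seed=1)
    curve, summary = mechanics.analyze_pull(exp)
    return default_truth, exp, curve, summary


@pytest.fixture(scope="session")
def straight_map():
    """Noiseless straight fibril height map, D-band off (pure half-cylinder)."""
    truth = synth.FibrilGroundTruth(segment_length_um=5.0, dband_depth_nm=0.0)
    return truth, synth.make_afm_map(truth, pixel_nm=8.0, noise_sd_nm=0.0,
                                     seed=0)


@pytest.fixture(scope="session")
def banded_map():
    """Noisy straight fibril with the 67 nm D-band at SNR 5."""
    truth = synth.FibrilGroundTruth(segment_length_um=10.0)
    return truth, synth.make_afm_map(truth, pixel_nm=8.0, noise_sd_nm=0.4,
                                     seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
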