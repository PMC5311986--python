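import numpy as np
import pytest

from freqclust import gen_multisubject, gen_oscillation, white_noise_series

#: Band specs for well-separated planted clusters, used across tests.
LOW_BAND = [(0.01, 0.03, 1.0)]
MID_BAND = [(0.03, 0.07, 1.0)]
HIGH_BAND = [(0.08, 0.18, 1.0)]
TOP_BAND = [(0.18, 0.24, 1.0)]


def planted_datasets(n_groups=2, n_rois=10, n_subjects=3, n=220, fs=0.5, seed=0):
    bands = [LOW_BAND, HIGH_BAND, MID_BAND, TOP_BAND][:n_groups]
    rois = list(range(1, n_rois + 1))
    spec = [(rois[g::n_groups], bands[g]) for g in range(n_groups)]
    return gen_multisubject(n_subjects, n_rois, spec, n=n, fs=fs, seed=seed)


@pytest.fixture
def two_group_datasets():
    return planted_datasets(n_groups=2, n_rois=10, n_subjects=3, seed=7)


@pytest.fixture
def tone():
    return gen_oscillation(0.05, amp=1.0, n=220, fs=0.5)


@pytest.fixture
def noise_ensemble():
    """White-noise ensemble at the study's series length and sampling rate."""
    return [white_noise_series(220, 0.5, seed=s) for s in range(200)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
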