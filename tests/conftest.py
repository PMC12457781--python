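import numpy as np
import pytest

import gaitphase as gp


@pytest.fixture(scope="session")
def default_profile():
    return gp.SubjectProfile(subject_id="S01", rng_seed=42)


@pytest.fixture(scope="session")
def small_recording(default_profile):
    """~30 strides of one synthetic subject."""
    return gp.simulate_subject(default_profile, 30)


@pytest.fixture(scope="session")
def small_cohort():
    """Six heterogeneous subjects, 40 strides each."""
    return gp.simulate_cohort(gp.default_cohort(6, base_seed=7), 40)


def make_separable_windows(n_per_class=150, Lw=50, D=12, seed=0):
    """Four noise-free, well-separated phase waveforms as labeled windows.

    Class k is a sinusoid bank with a class-specific offset; windows within
    a class differ only by a small deterministic time shift, so the task is
    cleanly separable.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(Lw) / Lw
    windows, labels = [], []
    for k in range(4):
        for j in range(n_per_class):
            shift = (j % 10) / 40.0
            base = np.sin(2 * np.pi * (k + 1) * (t[:, None] + shift) + np.arange(D) / 3.0)
            windows.append(base + (k - 1.5))
            labels.append(k)
    order = rng.permutation(len(labels))
    w = np.array(windows, dtype=np.float32)[order]
    y = np.array(labels, dtype=np.int64)[order]
    return gp.WindowSet(w, y, np.array(["X"] * len(y)), Lw)


@pytest.fixture(scope="session")
def separable_windows():
    return make_separable_windows()
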