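import numpy as np
import pytest

from ecgcluster.cohort import SubjectProfile, WaveParams, generate_clean_ecg
from ecgcluster.io import CONDITIONS


def make_profile(hr=60.0, rr_sd=0.0, waves=None, subject_id="s0"):
    return SubjectProfile(
        subject_id=subject_id,
        age=55.0,
        sex="M",
        flags={c: False for c in CONDITIONS},
        waves=waves or WaveParams.typical(),
        heart_rate_bpm=hr,
        rr_sd_ms=rr_sd,
    )


@pytest.fixture
def profile():
    return make_profile()


@pytest.fixture
def clean_signal(profile):
    """10 s at 1000 Hz, 60 bpm, zero RR variability: R apexes at 0.5, 1.5, ... s."""
    return generate_clean_ecg(profile, fs=1000.0, duration=10.0, seed=1)


def brute_force_min_sse(X: np.ndarray, k: int) -> float:
    """Exhaustive minimum of the k-means square error over every assignment
    of n points to at most k groups (independent of Lloyd's algorithm)."""
    import itertools

    n = X.shape[0]
    labels = np.array(list(itertools.product(range(k), repeat=n)))
    onehot = labels[:, :, None] == np.arange(k)  # (k^n, n, k)
    counts = onehot.sum(axis=1)  # (k^n, k)
    sums = np.einsum("pnk,nd->pkd", onehot.astype(float), X)
    norms = (sums**2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(counts > 0, norms / counts, 0.0)
    sse = float((X**2).sum()) - contrib.sum(axis=1)
    return float(sse.min())
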