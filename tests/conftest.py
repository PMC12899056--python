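import numpy as np
import pytest

from neoseiz.synth import CohortConfig, SubjectProfile, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_subjects_per_group=2, duration_s=60.0, seed=42,
                        burst_rate=4.0, burst_dur_range_s=(3.0, 6.0),
                        annotator_flip_prob=0.2)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def seizure_profile() -> SubjectProfile:
    return SubjectProfile(subject_id="sz01", amplitude_gain=2.0, spectral_tilt=1.0,
                          baseline_shift_hz=4.0, focal_channels=frozenset({6}),
                          group="seizure")


@pytest.fixture
def quiet_profile() -> SubjectProfile:
    return SubjectProfile(subject_id="ns01", amplitude_gain=1.0, spectral_tilt=1.0,
                          baseline_shift_hz=4.0, focal_channels=frozenset(),
                          group="non_seizure")


def numgrad(f, arr: np.ndarray, idxs=None, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar ``f()`` w.r.t. ``arr`` entries."""
    flat = arr.ravel()
    idxs = range(flat.size) if idxs is None else idxs
    out = []
    for i in idxs:
        old = flat[i]
        flat[i] = old + eps
        fp = f()
        flat[i] = old - eps
        fm = f()
        flat[i] = old
        out.append((fp - fm) / (2 * eps))
    return np.array(out)
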