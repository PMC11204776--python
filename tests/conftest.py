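import warnings

import pytest

from pivotshift.simulate import SimParams, simulate_cohort, simulate_recording_with_truth

# The printed worked example: three peaks with known amplitudes (rad/s) and
# locations (cs).
SUBJECT45_TIMES = [111.0, 267.0, 448.0]
SUBJECT45_AMPS = [137.54, 179.86, 156.83]


@pytest.fixture(scope="session")
def subject45():
    """Noise-free fixture recording built from the printed peak values."""
    params = SimParams(
        peak_times_cs=SUBJECT45_TIMES,
        peak_amplitudes=SUBJECT45_AMPS,
        noise_sd=0.0,
        seed=45,
    )
    rec, truth = simulate_recording_with_truth(params, "S45", "E1", 1)
    return rec, truth


@pytest.fixture(scope="session")
def small_session():
    """Small simulated cohort shared by I/O and reliability tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session, truth = simulate_cohort(
            {0: 2, 1: 2, 2: 2}, repeats_per_subject=2, seed=7
        )
    return session, truth


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort with the study's grade distribution (10/9/9/2), one rater."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session, truth = simulate_cohort(
            {0: 10, 1: 9, 2: 9, 3: 2}, seed=0, noise_frac=0.05
        )
    return session, truth
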