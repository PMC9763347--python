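import numpy as np
import pytest

from pupilwave import CohortSpec, Signal, TimeSeriesRecording, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_cohort():
    """4 subjects x 3 sessions of 512 samples with scattered missing
    values — just enough structure to exercise I/O round trips."""
    rng = np.random.default_rng(7)
    recordings = []
    for group, n in (("case", 2), ("control", 2)):
        for i in range(n):
            sessions = []
            for s in range(3):
                values = rng.normal(3.5, 0.3, size=512)
                mask = rng.random(512) < 0.1
                sessions.append(Signal(values=values, missing_mask=mask, session_index=s))
            recordings.append(
                TimeSeriesRecording(
                    participant_id=f"{group}{i}", group=group, sessions=sessions
                )
            )
    return recordings


@pytest.fixture(scope="session")
def small_cohort():
    """Separable two-group cohort small enough for fast pipeline tests:
    short sessions, clear Hurst separation."""
    spec = CohortSpec(
        n_cases=4, n_controls=4, H_case=0.6, H_control=0.95,
        sessions_per_subject=3, session_length=4096,
        missing_fraction=0.2, blink_burst_length=100, seed=11,
    )
    return simulate_cohort(spec)
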