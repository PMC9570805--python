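import numpy as np
import pytest

from sladl.cohort import (CohortConfig, ScheduleConfig, ParticipantProfile,
                          generate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_profile():
    return ParticipantProfile(
        participant_id="P00",
        amp_scale={"accel": 1.0, "gyro": 1.0, "emg": 1.0},
        freq_scale=1.0,
        phase_offset=0.0,
        posture_offset=0.0,
        emg_posture_refs=(1.0, 1.0),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants with short (5-7 s) activity blocks."""
    cfg = CohortConfig(n_participants=3,
                       schedule=ScheduleConfig(min_duration=5.0,
                                               max_duration=7.0))
    return generate_cohort(3, cfg, seed=77)
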