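import numpy as np
import pytest

from kesblock.recording_io import TrialCondition
from kesblock.synthetic_data import (
    BlockGroundTruth,
    MusclePhysiology,
    OnsetGroundTruth,
    make_protocol,
    simulate_recording,
)

#: sampling rate used for fast tests; analysis operates on physical time.
FS_TEST = 1000.0


@pytest.fixture
def quiet_phys() -> MusclePhysiology:
    """Deterministic muscle: no noise, drift, fatigue or facilitation."""
    return MusclePhysiology(
        noise_sd_n=0.0, drift_amplitude_n=0.0, fatigue_rate=0.0, recovery_rate_per_s=0.0
    )


@pytest.fixture
def truth_10khz() -> BlockGroundTruth:
    return BlockGroundTruth(sigma_true_ma=1.2, beta_true_per_ma=10.0)


@pytest.fixture
def no_onset() -> OnsetGroundTruth:
    return OnsetGroundTruth(onset_peak_n=0.0, onset_duration_s=0.0)


def sel_condition(freq_khz=10.0, amp_ma=1.2, fascicle="TF") -> TrialCondition:
    return TrialCondition(
        kes_frequency_khz=freq_khz,
        kes_amplitude_ma=amp_ma,
        protocol_kind="SEL",
        fascicle_a=fascicle,
    )


def simulate_sel(
    amp_ma,
    phys,
    truth,
    onset=None,
    seed=0,
    fs=FS_TEST,
    freq_khz=10.0,
    fascicle="TF",
    facilitation=False,
):
    protocol = make_protocol("SEL", sel_condition(freq_khz, amp_ma, fascicle))
    return simulate_recording(
        protocol, phys, truth, onset, seed=seed, sampling_rate_hz=fs,
        facilitation=facilitation,
    )
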