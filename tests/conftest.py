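import numpy as np
import pytest

from vgrfgait.io import default_layout
from vgrfgait.synthetic import GaitProfile, simulate_subject


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def clean_profile():
    """Deterministic, noiseless gait profile: exact programmed timings."""
    return GaitProfile(stride_time_cv=0.0, swing_fraction_cv=0.0,
                       sensor_noise_sd=0.0, swing_blip_rate=0.0)


@pytest.fixture(scope="session")
def noiseless_subject(clean_profile):
    """140 s noiseless walk with ~127 programmed strides + ground truth."""
    return simulate_subject(clean_profile, seed=11, duration=140.0,
                            subject_id="clean", group="control")


@pytest.fixture(scope="session")
def noisy_subject():
    """Default (noisy) control walk + ground truth."""
    return simulate_subject(GaitProfile(), seed=23, duration=140.0,
                            subject_id="noisy", group="control")


def make_record(left, right=None, sampling_rate=100.0, subject_id="t",
                group="control"):
    """Build a consistent in-memory record from (n, 8) force arrays."""
    from vgrfgait.io import VGRFRecord
    left = np.asarray(left, dtype=float)
    right = left.copy() if right is None else np.asarray(right, dtype=float)
    n = len(left)
    rec = VGRFRecord(subject_id=subject_id, group=group,
                     sampling_rate=sampling_rate,
                     time=np.arange(n) / sampling_rate,
                     left_forces=left, right_forces=right,
                     left_total=left.sum(axis=1), right_total=right.sum(axis=1))
    rec.validate()
    return rec
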