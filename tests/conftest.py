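import numpy as np
import pytest

from snoreacoustics.audioprep import SEGMENT_SAMPLES, TARGET_SR, AudioSegment
from snoreacoustics.synth import CohortSpec, synth_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 4+4-patient cohort with rendered audio, reused across tests."""
    return synth_cohort(CohortSpec(
        n_stenotic=4, n_non_stenotic=4,
        snore_segments_per_patient=3, non_snore_segments_per_patient=2,
        seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tone_segment(freq_hz, label=1, amp=0.5, patient_id="P1", group="stenotic"):
    t = np.arange(SEGMENT_SAMPLES) / TARGET_SR
    return AudioSegment(samples=amp * np.sin(2 * np.pi * freq_hz * t),
                        label=label, patient_id=patient_id, group=group)


@pytest.fixture()
def tone_factory():
    return tone_segment
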