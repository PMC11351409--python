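import logging

import numpy as np
import pytest

from qvor.io_vhit import Paradigm, VelocityTrace
from qvor.synthetic import CohortSimConfig, TraceSimConfig, generate_cohort, generate_trace

# silence per-recording cross-check chatter during the suite
logging.getLogger("qvor").setLevel(logging.ERROR)


def make_trace(
    *,
    duration_s: float = 17.0,
    sample_rate: float = 250.0,
    freq: float = 0.75,
    head_peak: float = 82.0,
    gain: float = 1.0,
    subject_id: str = "T",
    paradigm: Paradigm = Paradigm.VVOR,
) -> VelocityTrace:
    """Hand-built sinusoidal trace: eye = -gain * head, no noise."""
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    head = head_peak * np.sin(2 * np.pi * freq * t)
    return VelocityTrace(
        subject_id=subject_id,
        paradigm=paradigm,
        sample_rate=sample_rate,
        time=t,
        head_velocity=head,
        eye_velocity=-gain * head,
    )


@pytest.fixture
def vvor_trace():
    trace, _ = generate_trace(TraceSimConfig(true_gain=1.0, seed=11))
    return trace


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject simulated cohort used by pipeline-level tests."""
    return generate_cohort(CohortSimConfig(n_subjects=10, n_female=5, seed=7))
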