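import numpy as np
import pytest

from cpecast.synthetic import AdmissionSeries, GeneratorConfig, PainEvent, generate_cohort


def make_admission(events_hm_nrs, n_days=2, admit_minute=600,
                   patient="P1", admission="P1-A0"):
    """Build an admission from (day, hour, minute, nrs) tuples."""
    discharge = n_days * 1440
    evs = [PainEvent(patient, admission, d * 1440 + h * 60 + m, nrs)
           for d, h, m, nrs in events_hm_nrs]
    return AdmissionSeries(patient, admission, admit_minute, discharge, evs)


@pytest.fixture(scope="session")
def small_cohort():
    """30-patient calibrated cohort reused across tests (read-only)."""
    return generate_cohort(GeneratorConfig(n_patients=30, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
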