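import numpy as np
import pytest

from ventwave import (
    CohortSpec,
    PatientModel,
    VentilatorSettings,
    WaveformRecord,
    simulate_cohort,
)


def make_record(flow, pressure=None, sample_rate=50.0):
    """Build a WaveformRecord from a flow array (pressure defaults to 5 cmH2O)."""
    flow = np.asarray(flow, dtype=float)
    if pressure is None:
        pressure = np.full(len(flow), 5.0)
    time = np.arange(len(flow)) / sample_rate
    return WaveformRecord(time=time, pressure=pressure, flow=flow, sample_rate=sample_rate)


@pytest.fixture(scope="session")
def clean_cohort():
    """40 artifact-free noise-free breaths with ground truth."""
    return simulate_cohort(
        CohortSpec(n_breaths=40, seed=11, patient=PatientModel(noise_sd=0.0))
    )


@pytest.fixture(scope="session")
def mixed_cohort():
    """120 breaths with DTA, BSA and artifacts at realistic noise."""
    return simulate_cohort(
        CohortSpec(n_breaths=120, dta_pct=0.08, bsa_pct=0.10, artifact_pct=0.06, seed=5)
    )


@pytest.fixture(scope="session")
def vc_settings():
    return VentilatorSettings(mode="AC/VC", set_tv=500.0, rate=20.0, i_time=1.0)
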