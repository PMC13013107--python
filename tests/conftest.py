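import numpy as np
import pandas as pd
import pytest

from pam.align_stratify import W24_48
from pam.cohort_io import FeatureMatrix, PatientRecord, SampleRecord
from pam.synth_cohort import SpikeSpec, SynthConfig, generate_cohort


def make_patient(pid, event=False, event_day=None, age=60.0, sex="F",
                 loc="anterior", hh=3, mf=3, **outcomes) -> PatientRecord:
    return PatientRecord(patient_id=pid, age=age, sex=sex,
                         aneurysm_location=loc, hunt_hess=hh, mfisher=mf,
                         event_status=event, event_day=event_day, **outcomes)


def make_sample(sid, pid, day, hour=None) -> SampleRecord:
    return SampleRecord(sample_id=sid, patient_id=pid, day_post_index=day,
                        hour_post_index=hour)


def exact_moments_vector(mean: float, sd: float, n: int) -> np.ndarray:
    """A length-n vector with exactly the given mean and sample SD (ddof=1)."""
    z = np.arange(n, dtype=float)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-patient synthetic cohort with one strong planted depletion."""
    cfg = SynthConfig(
        n_patients=16, n_features=40, seed=11,
        spikes=[SpikeSpec("ARG", {W24_48: -1.5},
                          base_log_mean=25.0, base_log_sd=0.5)])
    patients, samples, matrix, truth = generate_cohort(cfg)
    return cfg, patients, samples, matrix, truth


@pytest.fixture()
def raw_matrix():
    rng = np.random.default_rng(5)
    data = pd.DataFrame(rng.uniform(1.0, 100.0, size=(6, 4)),
                        index=[f"S{i}" for i in range(6)],
                        columns=[f"F{j}" for j in range(4)])
    return FeatureMatrix(data)
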