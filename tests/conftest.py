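import numpy as np
import pytest

from chorscore import PatientRecord, mayo_default_config, simulate_cohort


def make_record(**kwargs):
    """A minimally valid record; involvement defaults to heart + kidney."""
    defaults = dict(
        patient_id="P1",
        heart_involved=True,
        kidney_involved=True,
        baseline_dflc=19.0,
        landmark_dflc=10.0,
        landmark_ifix_negative=False,
        landmark_flc_ratio_normal=False,
        baseline_ntprobnp=2000.0,
        landmark_ntprobnp=1300.0,
        baseline_proteinuria=5000.0,
        landmark_proteinuria=3000.0,
        baseline_egfr=65.0,
        landmark_egfr=60.0,
        os_time=48.0,
        os_event=False,
        dialysis_time=48.0,
        dialysis_event=False,
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_mayo_cohort():
    """A seeded 600-patient Mayo-like cohort shared across tests."""
    cfg = mayo_default_config(n_patients=600, seed=11)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth
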