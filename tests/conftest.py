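import numpy as np
import pytest

from carpop.synthetic_data import (ObservationSchedule, default_patient,
                                   default_truth_population, generate_cohort,
                                   zero_noise)


@pytest.fixture
def params():
    return default_patient()


@pytest.fixture
def daily_grid():
    return np.linspace(0.0, 30.0, 31)


@pytest.fixture(scope="session")
def dense_noise_free_patient():
    """One patient with daily noise-free observations of every stream."""
    days = tuple(range(31))
    sched = ObservationSchedule(blood_days=days, phenotype_days=days,
                                spd_days=days, ldh_days=days,
                                cytokine_days=(0, 28))
    ds = generate_cohort(zero_noise(default_truth_population()), n_patients=1,
                         schedule=sched, seed=42)
    pid = ds.patient_ids()[0]
    return ds, pid


@pytest.fixture(scope="session")
def noisy_cohort_20():
    """Default-schedule noisy cohort of 20 patients."""
    return generate_cohort(default_truth_population(), n_patients=20, seed=7)


def random_patients(n, seed=0):
    """Random valid parameter draws from the default truth population."""
    from carpop.population import draw_vpop
    return draw_vpop(default_truth_population(), n, seed, default_patient())
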