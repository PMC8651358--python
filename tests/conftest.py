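import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from drmsm.cohort import Cohort, PatientSeries, VisitRecord
from drmsm.ctmc import CovariateModel, CovariateSchedule, homogeneous_model
from drmsm.simulate import DEFAULT_BASELINE_RATES

#: The study-level at-mean-covariates intensities used as generating truth.
TRUTH_RATES = dict(DEFAULT_BASELINE_RATES)


def make_series(patient_id, times, stages, hba1c=None, **baseline):
    """Hand-rolled patient series for unit tests."""
    hba1c = hba1c if hba1c is not None else [8.0] * len(times)
    visits = [
        VisitRecord(t=float(t), stage=int(s), hba1c=float(h) if h is not None else math.nan)
        for t, s, h in zip(times, stages, hba1c)
    ]
    defaults = dict(age=56.0, female=0.0, hispanic=0.0, dm_duration=13.0, hypertension=1.0)
    defaults.update(baseline)
    return PatientSeries(patient_id=patient_id, visits=visits, **defaults)


@pytest.fixture
def homogeneous_truth():
    """Covariate-free model at the study's at-mean intensities."""
    return homogeneous_model(TRUTH_RATES)


@pytest.fixture
def flat_schedule():
    """A trivial empty-covariate schedule covering [0, 30]."""
    return CovariateSchedule(
        breakpoints=np.array([0.0, 30.0]), values=np.zeros((1, 0)), names=()
    )


@pytest.fixture
def hba1c_model():
    """Single-covariate (HbA1c) model with hazard ratio 1.10 per point."""
    base = homogeneous_model(TRUTH_RATES)
    return CovariateModel(
        theta=base.theta,
        beta=np.array([np.log(1.10)]),
        covariates=("hba1c",),
        centering={"hba1c": 9.7},
    )


@pytest.fixture
def hba1c_schedule():
    """Piecewise HbA1c path: 9.7 on [0,2), 11.0 on [2,5)."""
    return CovariateSchedule(
        breakpoints=np.array([0.0, 2.0, 5.0]),
        values=np.array([[9.7], [11.0]]),
        names=("hba1c",),
    )


def toy_cohort():
    """Three eligible patients with four visits each, complete covariates."""
    patients = [
        make_series("a", [0, 1, 2, 3], [1, 1, 2, 2], hba1c=[9.0, 8.5, 8.0, 8.0]),
        make_series("b", [0, 1.2, 2.1, 3.3], [2, 2, 3, 5], hba1c=[10.0, 10.5, 9.0, 9.0],
                    hispanic=1.0),
        make_series("c", [0, 0.9, 2.2, 4.0], [1, 2, 4, 4], hba1c=[11.0, 10.0, 10.0, 9.5],
                    female=1.0),
    ]
    from drmsm.cohort import _flag_eligibility

    for p in patients:
        _flag_eligibility(p)
    return Cohort(patients=patients)


@pytest.fixture
def small_cohort():
    return toy_cohort()
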