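import numpy as np
import pandas as pd
import pytest

from lungrisk import cohort as C
from lungrisk import registry as R


@pytest.fixture(scope="session")
def registry():
    return R.default_registry()


@pytest.fixture(scope="session")
def model_2016(registry):
    return R.get_model(registry, "2016E1")


@pytest.fixture()
def baseline_patient():
    """60-year-old man, ppoFEV1% 76, VATS lobectomy, no comorbidity."""
    return {
        "age": 60,
        "sex": "male",
        "ppo_fev1_percent": 76.0,
        "fvc_percent": 90.0,
        "approach": "VATS",
        "extended_resection": False,
        "cad": False,
        "cvd": False,
        "ckd": False,
        "copd": False,
        "diabetes": False,
    }


@pytest.fixture(scope="session")
def study_cohort():
    """Default-size (n=1085) synthetic cohort with outcomes."""
    return C.generate_study_cohort(C.CohortSimulationConfig())


@pytest.fixture(scope="session")
def large_cohort(model_2016):
    """n=20000 cohort whose outcomes come from the 2016E1 model's own
    predictions (no intercept shift), for self-consistency checks."""
    cfg = C.CohortSimulationConfig(n=20000, seed=7)
    cov = C.sample_cohort(cfg)
    from scipy.special import expit

    own_rate = float(expit(R.linear_predictor_cohort(model_2016, cov)).mean())
    return C.assign_outcomes(cov, model_2016, own_rate, seed=8)
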