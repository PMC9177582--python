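import numpy as np
import pytest

import metaspread as ms

# One shared parameter-recovery experiment: a registry-like cohort simulated
# from the default (published-where-printed) rates, and its maximum-likelihood
# refit.  Session-scoped because the fit is the expensive step.
RECOVERY_N = 100_000
RECOVERY_SEED = 0


@pytest.fixture(scope="session")
def theta_true() -> ms.RateVector:
    return ms.DEFAULT_TRUE_RATES


@pytest.fixture(scope="session")
def recovery_cohort() -> ms.Cohort:
    return ms.generate_cohort(ms.SimConfig(n_patients=RECOVERY_N, seed=RECOVERY_SEED))


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort) -> ms.FitResult:
    return ms.fit_mle(recovery_cohort, seed=1)


@pytest.fixture(scope="session")
def small_cohort() -> ms.Cohort:
    return ms.generate_cohort(ms.SimConfig(n_patients=400, seed=3))


@pytest.fixture()
def cohort_csv(tmp_path):
    """A tiny well-formed cohort CSV on disk."""
    path = tmp_path / "cohort.csv"
    path.write_text(
        "patient_id,diameter_mm,met_bone,met_lung,met_liver,met_brain,er,pr,her2\n"
        "p1,12.0,0,0,0,0,pos,neg,neg\n"
        "p2,35.5,1,0,0,1,neg,neg,pos\n"
        "p3,8.2,0,1,0,0,neg,pos,neg\n"
    )
    return path
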