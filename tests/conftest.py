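import numpy as np
import pytest

import panelmsm as pm


@pytest.fixture(scope="session")
def structure():
    """The four-state breast-cancer progression structure."""
    return pm.breast_cancer_structure()


@pytest.fixture(scope="session")
def two_state():
    """Minimal live/dead chain: one transition, one absorbing state."""
    return pm.TransitionStructure(
        n_states=2, allowed=((1, 2),), state_labels=("alive", "dead")
    )


# Moderate, well-identified generating rates used throughout the estimator
# validation tests (all between 0.08 and 0.3 per year, resolvable by annual
# visits over 8 years of follow-up).
VALIDATION_RATES = {
    (1, 2): 0.25,
    (1, 3): 0.12,
    (1, 4): 0.08,
    (2, 3): 0.10,
    (2, 4): 0.10,
    (3, 2): 0.15,
    (3, 4): 0.30,
}


@pytest.fixture(scope="session")
def validation_model(structure):
    lb = np.log([VALIDATION_RATES[p] for p in structure.allowed])
    params = pm.ModelParameters(log_baseline=lb)
    return pm.TrueModel(structure=structure, params=params)


@pytest.fixture(scope="session")
def annual_schedule():
    return pm.VisitSchedule(
        scheme="fixed-interval", interval_years=1.0, max_followup_years=8.0
    )


@pytest.fixture(scope="session")
def small_cohort(validation_model, annual_schedule):
    """A 150-subject cohort from the validation model (shared, read-only)."""
    return pm.generate_cohort(validation_model, 150, annual_schedule, seed=321)
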