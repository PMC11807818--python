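import numpy as np
import pandas as pd
import pytest

from diisurv.cohort import build_cohort
from diisurv.dietary_scoring import DIIReferenceTable
from diisurv.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def reference():
    return DIIReferenceTable.default()


@pytest.fixture(scope="session")
def sim_tables():
    """One moderate synthetic cohort shared across read-only tests."""
    return generate_cohort(SimulationConfig(n=12_000, seed=7))


@pytest.fixture(scope="session")
def cohort(sim_tables):
    df, _ = build_cohort(sim_tables["intakes"], sim_tables["covariates"],
                         sim_tables["followup"])
    return df


def make_survival_frame(rng, n, beta=0.0, quad=0.0, rate=1e-3,
                        admin_censor=300.0, exposure=None):
    """Simple exponential-hazard survival data with a single exposure."""
    x = rng.standard_normal(n) if exposure is None else np.asarray(exposure)
    lam = rate * np.exp(beta * x + quad * x * x)
    T = rng.exponential(1.0 / lam)
    t = np.minimum(T, admin_censor)
    ev = np.where(T <= admin_censor, "cld", "censored")
    return pd.DataFrame({"dii": x, "follow_up_weeks": t, "event": ev})


@pytest.fixture
def survival_frame_factory():
    return make_survival_frame
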