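import numpy as np
import pandas as pd
import pytest

from dntp.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 64 patients, 32/32 arms."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def interaction_cohort():
    """A 300-patient cohort with one strong planted interaction gene."""
    cfg = SyntheticConfig(n_patients=300, n_genes=10,
                          beta_inter={"G0001": 1.2}, seed=20240601)
    return generate_cohort(cfg)


@pytest.fixture
def hand_survival():
    """A 12-subject single-binary-covariate dataset for oracle checks."""
    rng = np.random.default_rng(7)
    time = rng.exponential(10.0, 12).round(2) + 0.5
    event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 1, 0])
    x = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
    return time, event, pd.DataFrame({"x": x})
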