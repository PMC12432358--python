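import numpy as np
import pandas as pd
import pytest

from methrisk import MethylationMatrix, PhenotypeTable, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def survival_fixture(rng):
    """A 20-subject tie-free survival dataset with 3 covariates."""
    n = 20
    x = rng.normal(size=(n, 3))
    t_event = rng.exponential(4.0 * np.exp(-x @ np.array([0.6, -0.4, 0.2])))
    censor = np.minimum(rng.exponential(6.0, n), 7.2)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    # guarantee a usable mix of events and censorings
    event[:3] = 1
    assert 0 < event.sum() < n
    return x, time, event


@pytest.fixture
def tiny_matrix():
    values = np.array([[0.2, 0.3], [0.5, 0.6], [0.8, 0.7]])
    return MethylationMatrix(["cg1", "cg2", "cg3"], ["s1", "s2"], values, "beta")


def make_phenotypes(n, events, times, rng=None, genders=None):
    rng = rng or np.random.default_rng(0)
    genders = genders if genders is not None else \
        np.where(rng.random(n) < 0.5, "male", "female")
    return PhenotypeTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "event": events, "time_years": times,
        "age": rng.normal(60, 10, n), "gender": genders,
        "bmi": rng.normal(31, 5, n), "hba1c": rng.normal(64, 15, n),
        "smoking_proxy": rng.uniform(0.5, 0.9, n),
        "med_diabetes": rng.integers(0, 2, n),
        "med_lipid": rng.integers(0, 2, n),
        "med_antihypertensive": rng.integers(0, 2, n),
    }))


@pytest.fixture
def null_cohort():
    """Cohort with no planted methylation signal (cached per session)."""
    cfg = SimulationConfig(n_subjects=400, n_sites=120, n_causal_sites=0, seed=5)
    return simulate_cohort(cfg)
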