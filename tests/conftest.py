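import numpy as np
import pandas as pd
import pytest

from grassipm import default_truth, generate_census
from grassipm.census import validate_individuals, validate_subplots
from grassipm.params import VitalRateParams
from grassipm.synthetic import DEFAULT_PARAM_VALUES


@pytest.fixture(scope="session")
def small_truth():
    """Small but fully featured census design (fast to generate/fit)."""
    return default_truth(seed=11, n_individuals=250, n_plots=5, n_subplots=4, n_years=2)


@pytest.fixture(scope="session")
def small_census(small_truth):
    ind, sub, heads = generate_census(small_truth)
    return validate_individuals(ind), validate_subplots(sub), heads


@pytest.fixture(scope="session")
def truth_params():
    """One ground-truth parameter set (the generator defaults)."""
    return VitalRateParams(**DEFAULT_PARAM_VALUES, stratum="truth")


@pytest.fixture()
def degenerate_tables():
    """A census where every individual row and every subplot-year row is
    identical, so any resample reproduces the data exactly."""
    n = 30
    ind = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(n)],
            "species": "syn",
            "year": 2018,
            "plot": "p1",
            "subplot": "p1-s1",
            "climate": "ambient",
            "management": "grazing",
            "size_t0": 5.0,
            "survived": True,
            "size_t1": 6.0,
            "reproductive": True,
            "seed_heads": 2,
            "seeds_total": 30.0,
            "is_new": True,
        }
    )
    sub = pd.DataFrame(
        {
            "species": "syn",
            "year": [2018],
            "plot": "p1",
            "subplot": "p1-s1",
            "climate": "ambient",
            "management": "grazing",
            "total_seeds": 900.0,
            "fall_seedlings": 30,
            "spring_seedlings": 15,
            "new_plants": 10,
        }
    )
    heads = pd.DataFrame(
        {"species": "syn", "plot": ["p1", "p1"], "head_id": ["h1", "h2"],
         "seed_count": [15, 15]}
    )
    return validate_individuals(ind), validate_subplots(sub), heads


def make_individuals(
    z,
    survived,
    z1=None,
    reproductive=None,
    seed_heads=None,
    climate="ambient",
    management="grazing",
    plot=None,
    is_new=None,
):
    """Hand-built individuals table from arrays (helper for unit tests)."""
    z = np.asarray(z, float)
    n = len(z)
    survived = np.asarray(survived, bool)
    if z1 is None:
        z1 = z.copy()
    z1 = np.asarray(z1, float)
    reproductive = (
        np.zeros(n, bool) if reproductive is None else np.asarray(reproductive, bool)
    )
    seed_heads = (
        np.zeros(n, int) if seed_heads is None else np.asarray(seed_heads, int)
    )
    df = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(n)],
            "species": "syn",
            "year": 2018,
            "plot": plot if plot is not None else "p1",
            "subplot": "s1",
            "climate": climate,
            "management": management,
            "size_t0": np.exp(z),
            "survived": survived,
            "size_t1": np.where(survived, np.exp(z1), np.nan),
            "reproductive": reproductive,
            "seed_heads": seed_heads,
            "seeds_total": 0.0,
            "is_new": np.zeros(n, bool) if is_new is None else np.asarray(is_new, bool),
        }
    )
    return validate_individuals(df)
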