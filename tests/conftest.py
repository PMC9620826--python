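import numpy as np
import pandas as pd
import pytest

from phers import (SimulationConfig, load_bundled_maps, simulate_cohort)


@pytest.fixture(scope="session")
def maps():
    return load_bundled_maps()


@pytest.fixture(scope="session")
def small_cohort(maps):
    """A small simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(n_persons=400, seed=11)
    cfg.disease_signal[0].n_cases = 20
    return simulate_cohort(cfg, maps=maps)


def make_demographics(n, seed=0, **extra):
    """Handcrafted demographics frame with derivable covariates."""
    rng = np.random.default_rng(seed)
    first = pd.to_datetime("2010-01-01") + pd.to_timedelta(
        rng.integers(0, 1000, n), unit="D")
    span = rng.integers(30, 4000, n)
    df = pd.DataFrame({
        "person_id": [f"H{i:03d}" for i in range(n)],
        "sex": rng.choice(["female", "male"], n),
        "first_visit_date": first,
        "last_visit_date": first + pd.to_timedelta(span, unit="D"),
        "age_first_visit": rng.uniform(1, 85, n),
    })
    for k, v in extra.items():
        df[k] = v
    return df


def icd_frame(rows):
    """Rows of (person, code, flag, iso-date) -> icd_occurrences frame."""
    df = pd.DataFrame(rows, columns=["person_id", "icd_code", "flag",
                                     "occurrence_date"])
    df["occurrence_date"] = pd.to_datetime(df["occurrence_date"])
    df["flag"] = df["flag"].astype("int64")
    return df
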