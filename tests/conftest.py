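import numpy as np
import pandas as pd
import pytest

import curemix as cm


def make_cohort(time, event, covariates: dict | None = None, **schema_kwargs) -> cm.Cohort:
    """Small hand-built cohort; covariates default to a single zero column."""
    time = np.asarray(time, dtype=float)
    covariates = covariates if covariates is not None else {"x": np.zeros_like(time)}
    data = pd.DataFrame({"subject_id": [f"s{i}" for i in range(len(time))], "time": time, "event": event})
    for k, v in covariates.items():
        data[k] = np.asarray(v, dtype=float)
    schema = cm.CovariateSchema(list(covariates), **schema_kwargs)
    return cm.Cohort(data, schema)


@pytest.fixture(scope="session")
def small_sim():
    """One mid-sized cohort from the default HIV-like generator."""
    cfg = cm.default_hiv_config(n=700, seed=11)
    return cm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def ph_fit(small_cohort):
    return cm.fit_mixture_cure_ph(small_cohort)


@pytest.fixture(scope="session")
def frailty_fit(small_cohort):
    return cm.fit_mixture_cure_frailty(small_cohort, max_iter=2500)
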