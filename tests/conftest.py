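import numpy as np
import pandas as pd
import pytest

from dmtrank import glm, simulate


@pytest.fixture(scope="session")
def small_registry():
    """One synthetic registry reused across fitting tests."""
    cfg = simulate.SimConfig(n_patients=600, n_sites=8, seed=3)
    cycles, trajectories, truth = simulate.generate_registry(cfg)
    return cycles, trajectories, truth


FAST_MCMC = glm.MCMCConfig(chains=2, warmup=400, post=200, draws=400, seed=0)


@pytest.fixture(scope="session")
def fit_relapse_prognostic(small_registry):
    cycles, _, _ = small_registry
    spec = glm.ModelSpec("relapse", "prognostic")
    return glm.fit(spec, cycles, mcmc=FAST_MCMC)


@pytest.fixture(scope="session")
def fit_relapse_predictive(small_registry):
    cycles, _, _ = small_registry
    spec = glm.ModelSpec("relapse", "predictive")
    return glm.fit(spec, cycles, mcmc=FAST_MCMC)


@pytest.fixture(scope="session")
def fit_cdp_prognostic(small_registry):
    cycles, _, _ = small_registry
    spec = glm.ModelSpec("cdp", "prognostic")
    return glm.fit(spec, cycles, mcmc=FAST_MCMC)


def make_cycles(**overrides) -> pd.DataFrame:
    """Small hand-built cycle table with valid defaults, for filter tests."""
    base = {
        "patient_id": ["P1", "P2", "P3", "P4"],
        "site_id": ["A", "A", "B", "B"],
        "index_dmt": ["DMF", "FTY", "GA", "NA"],
        "current_dmt": ["NONE", "DMF", "IF", "NONE"],
        "age": [30.0, 45.0, 28.0, 52.0],
        "gender": ["F", "M", "F", "F"],
        "edss_baseline": [2.0, 3.5, 1.0, 5.0],
        "diagnosis_distance": [4.0, 8.0, 2.0, 11.0],
        "relapse_distance": [0.5, 1.2, 0.4, 2.0],
        "relapses_count": [1, 2, 1, 0],
        "dmts_count": [0, 1, 2, 0],
        "second_line": [False, False, True, False],
        "current_duration": [0.0, 1.5, 2.0, 0.0],
        "index_duration": [1.0, 2.0, 1.5, 3.0],
        "n_relapses": [1, 0, 2, 1],
        "cdp": [False, False, True, False],
    }
    base.update(overrides)
    n = len(base["patient_id"])
    return pd.DataFrame({k: (v[:n] if isinstance(v, list) else v) for k, v in base.items()})
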