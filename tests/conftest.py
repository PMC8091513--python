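import numpy as np
import pandas as pd
import pytest

from phasetwo import default_scenario, simulate_cohort


def make_cohort(obs_time, event, **covs) -> pd.DataFrame:
    """Hand-built cohort table for toy examples."""
    n = len(obs_time)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "obs_time": np.asarray(obs_time, dtype=float),
            "event": np.asarray(event, dtype=int),
        }
    )
    for name in ("x_bm", "x_conf", "x_risk", "x_surr"):
        df[name] = np.asarray(covs.get(name, np.zeros(n, dtype=int)), dtype=int)
    return df


@pytest.fixture()
def toy_riskset_cohort() -> pd.DataFrame:
    # A: event at 1, B: event at 2, C: censored at 3, D: censored at 1.5
    return make_cohort([1.0, 2.0, 3.0, 1.5], [1, 1, 0, 0])


@pytest.fixture()
def toy_cm_cohort() -> pd.DataFrame:
    # A: event at 1 in stratum 1; B: censored 2 in stratum 0; C: censored 3 in stratum 1
    return make_cohort([1.0, 2.0, 3.0], [1, 0, 0], x_surr=[1, 0, 1])


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A fixed 20-subject cohort for Monte-Carlo selection-frequency oracles."""
    cfg = default_scenario(n_phase1=20, phase2_n=10, censor_rate=0.1)
    return simulate_cohort(cfg, seed=2024)


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    cfg = default_scenario(censor_rate=0.1)
    return simulate_cohort(cfg, seed=7)
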