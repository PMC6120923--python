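import warnings

import numpy as np
import pandas as pd
import pytest

from socialddm.ddm import DDMParams, drift_rates
from socialddm.simulate import simulate_wiener
from socialddm.task_design import full_design, generate_base_games


@pytest.fixture(autouse=True)
def _quiet():
    # fits on tiny synthetic subjects legitimately emit small-sample and
    # separation warnings; keep test output readable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def base_games():
    return generate_base_games(seed=1)


@pytest.fixture(scope="session")
def design():
    """All four blocks (free1, pressure, delay, free2) for one seed."""
    return full_design(seed=11)


@pytest.fixture(scope="session")
def free_games(design):
    return design[design["condition"].isin(["free1", "free2"])]


def simulate_subject_trials(params: DDMParams, games: pd.DataFrame,
                            seed: int, dt: float = 0.002) -> pd.DataFrame:
    """Time-free trials of one synthetic subject under ``params``."""
    rng = np.random.default_rng(seed)
    v = drift_rates(params, games)
    res = simulate_wiener(len(games), v, params.a, params.z, dt=dt,
                          szr=params.szr, rng=rng, bridge=True)
    out = games[["game_id", "condition", "dic_diff", "rece_diff"]].copy()
    out["subject_id"] = 1
    out["choice"] = np.where(res.choice_selfish, "selfish", "prosocial")
    out["rt"] = res.decision_time + params.t0
    out["censored"] = False
    return out


@pytest.fixture(scope="session")
def subject_trials_factory():
    return simulate_subject_trials
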