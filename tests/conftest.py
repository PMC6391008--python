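import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from twostage import DDMRLParams, RLParams, TaskConfig, simulate_agent
from twostage.task import SessionData

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_session(choice1, transition, choice2, reward, rt1=None, rt2=None,
                 block=None, subject_id="s", timepoint="t1",
                 p_common=0.7) -> SessionData:
    """Build a session from compact per-trial lists.

    ``state2`` is derived from (choice1, transition) under the fixed
    mapping: choice 1 commonly leads to state 2, choice 2 to state 3.
    """
    n = len(choice1)
    c1 = np.asarray(choice1)
    state2 = np.where(np.asarray(transition) == "common", c1 + 1, 4 - c1)
    trials = pd.DataFrame({
        "block": block if block is not None else np.ones(n, dtype=int),
        "trial": np.arange(1, n + 1),
        "choice1": c1,
        "transition": transition,
        "state2": state2,
        "choice2": choice2,
        "reward": reward,
        "rt1": rt1 if rt1 is not None else np.full(n, np.nan),
        "rt2": rt2 if rt2 is not None else np.full(n, np.nan),
    })
    cfg = TaskConfig(n_trials=n, p_common=p_common,
                     n_blocks=int(trials["block"].nunique()))
    return SessionData(subject_id, timepoint, cfg, trials)


@pytest.fixture(scope="session")
def rl_params():
    return RLParams(alpha1=0.6, alpha2=0.35, beta1=5.0, beta2=4.0,
                    lam=0.5, w=0.8, p=0.15)


@pytest.fixture(scope="session")
def ddm_params():
    return DDMRLParams(alpha1=0.6, alpha2=0.35, lam=0.5, w=0.8, p=0.15,
                       b1=4.0, a1=1.5, tau1=0.3, b2=5.0, a2=2.0, tau2=0.25)


@pytest.fixture(scope="session")
def rl_session(rl_params):
    return simulate_agent(rl_params, TaskConfig(n_trials=200), seed=3)


@pytest.fixture(scope="session")
def ddm_session(ddm_params):
    return simulate_agent(ddm_params, TaskConfig(n_trials=200), seed=4)


@pytest.fixture(scope="session")
def ddm_cohort():
    from twostage.psychometrics import simulate_cohort
    return simulate_cohort("ddm11", n_agents=24, n_trials=150, seed=50)
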