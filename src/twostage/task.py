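"""Two-stage task structures and the generative environment.

The task: on each trial a first-stage choice between two options leads,
with fixed probabilities (70% "common" / 30% "rare"), to one of two
second-stage states, each offering a pair of bandits whose reward
probabilities drift as independent reflected Gaussian random walks; the
second-stage choice yields a binary reward.  Option 1 leads to state 2 and
option 2 to state 3 on a common transition (a fixed labelling convention;
the task itself is symmetric under relabelling).

Agents are simulated closed-loop: the hybrid learner's values are updated
each trial from the events the agent itself generated, with choices drawn
either from the softmax rule (choice-only model) or from the sampled
diffusion first passage (choice + RT model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernels as K
from .params import DDMRLParams, RLParams

__all__ = [
    "TaskConfig",
    "RewardWalk",
    "TrialRecord",
    "SessionData",
    "generate_reward_walks",
    "sample_transition",
    "simulate_agent",
    "block_ids",
    "pack_session",
]

#: columns of the per-trial table carried by SessionData
TRIAL_COLUMNS = ["block", "trial", "choice1", "transition", "state2",
                 "choice2", "reward", "rt1", "rt2"]


@dataclass(frozen=True)
class TaskConfig:
    """Static design of a session.

    Defaults follow the canonical task: 70/30 transitions, reward
    probabilities drifting by Gaussian steps of SD 0.025 reflected at
    [0.25, 0.75], two blocks separated by a mid-session break, binary
    rewards, and no response deadline imposed on simulated agents (so the
    generative model matches the fitted likelihood, which has no censoring
    term).
    """

    n_trials: int
    p_common: float = 0.7
    n_blocks: int = 2
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    deadline_s: Optional[float] = None
    reward_values: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if not (self.n_trials >= 2):
            raise ValueError("n_trials must be at least 2")
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError("p_common must lie in (0.5, 1]")
        lo, hi = self.walk_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("walk_bounds must satisfy 0 <= low < high <= 1")
        if not (self.walk_sd >= 0.0):
            raise ValueError("walk_sd must be non-negative")
        if not (1 <= self.n_blocks <= self.n_trials):
            raise ValueError("n_blocks must be in [1, n_trials]")
        if self.deadline_s is not None and not (self.deadline_s > 0):
            raise ValueError("deadline_s must be positive when given")


@dataclass(frozen=True)
class RewardWalk:
    """Reward probabilities of the four bandits, shape (4, n_trials).

    Bandit index is 2*(state - 2) + (choice2 - 1): bandits 0-1 live in
    state 2, bandits 2-3 in state 3.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must have shape (4, n_trials)")


@dataclass(frozen=True)
class TrialRecord:
    """One trial; RTs are NaN for choice-only simulations."""

    subject_id: str
    timepoint: str
    trial: int
    block: int
    choice1: int
    transition: str
    state2: int
    choice2: int
    reward: int
    rt1: float = float("nan")
    rt2: float = float("nan")


@dataclass
class SessionData:
    """All trials of one subject at one timepoint plus the task config."""

    subject_id: str
    timepoint: str
    config: TaskConfig
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table misses columns {missing}")
        tr = self.trials["trial"].to_numpy()
        if tr.size and np.any(np.diff(tr) <= 0):
            raise ValueError("trial indices must be strictly increasing")
        validate_transitions(self.trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def records(self) -> list[TrialRecord]:
        return [TrialRecord(self.subject_id, self.timepoint,
                            int(r.trial), int(r.block), int(r.choice1),
                            str(r.transition), int(r.state2), int(r.choice2),
                            int(r.reward), float(r.rt1), float(r.rt2))
                for r in self.trials.itertuples(index=False)]

    def truncate(self, n: int) -> "SessionData":
        """First ``n`` trials (used by reliability-vs-trials curves)."""
        return SessionData(self.subject_id, self.timepoint, self.config,
                           self.trials.iloc[:n].reset_index(drop=True))


def common_destination(choice1: int) -> int:
    """State reached by ``choice1`` on a common transition (1->2, 2->3)."""
    return choice1 + 1


def validate_transitions(trials: pd.DataFrame) -> None:
    """Check the transition labels against (choice1, state2) row-wise."""
    c1 = trials["choice1"].to_numpy(dtype=int)
    s2 = trials["state2"].to_numpy(dtype=int)
    lab = trials["transition"].to_numpy()
    is_common = s2 == c1 + 1
    expect = np.where(is_common, "common", "rare")
    bad = np.nonzero(expect != lab)[0]
    if bad.size:
        raise ValueError(
            f"transition label inconsistent with (choice1, state2) at row {bad[0]}")


def block_ids(n_trials: int, n_blocks: int) -> np.ndarray:
    """Block index per trial; blocks split the session as evenly as possible
    (two blocks -> break at the midpoint)."""
    return np.repeat(np.arange(n_blocks),
                     np.diff(np.linspace(0, n_trials, n_blocks + 1).round().astype(int)))


def generate_reward_walks(config: TaskConfig, seed: int) -> RewardWalk:
    """Draw the four reflected Gaussian reward-probability trajectories.

    Initial values are uniform within the bounds; each step adds
    N(0, walk_sd^2) and reflects at the bounds.
    """
    lo, hi = config.walk_bounds
    probs = K.gen_walk(config.n_trials, config.walk_sd, lo, hi,
                       _kernel_seed(seed))
    return RewardWalk(probs)


def sample_transition(choice1: int, config: TaskConfig,
                      rng: np.random.Generator) -> int:
    """Sample the second-stage state (2 or 3) for a first-stage choice."""
    if choice1 not in (1, 2):
        raise ValueError("choice1 must be 1 or 2")
    common = rng.random() < config.p_common
    return common_destination(choice1) if common else common_destination(3 - choice1)


def _kernel_seed(seed: int) -> int:
    """Map an arbitrary user seed to a 31-bit kernel seed."""
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))


def simulate_agent(params: Union[RLParams, DDMRLParams], config: TaskConfig,
                   seed: int, subject_id: str = "sim",
                   timepoint: str = "t1") -> SessionData:
    """Closed-loop simulation of one session.

    The reward walk and the agent's trajectory are both derived
    deterministically from ``seed``.  RLParams agents choose by softmax and
    carry no RTs; DDMRLParams agents choose by sampled diffusion first
    passage, with rt = decision time + non-decision time.
    """
    ss = np.random.SeedSequence(seed)
    walk_seed, agent_seed = (int(s % (2**31 - 1))
                             for s in ss.generate_state(2))
    lo, hi = config.walk_bounds
    walk = K.gen_walk(config.n_trials, config.walk_sd, lo, hi, walk_seed)
    blocks = block_ids(config.n_trials, config.n_blocks)

    if isinstance(params, RLParams):
        c1, s2, trans, c2, rew = K.simulate_rl(
            walk, blocks, config.p_common,
            params.alpha1, params.alpha2, params.beta1, params.beta2,
            params.lam, params.w, params.p, agent_seed)
        rt1 = np.full(config.n_trials, np.nan)
        rt2 = np.full(config.n_trials, np.nan)
    elif isinstance(params, DDMRLParams):
        from .ddm import _table_args
        tab, dk, du, umax, nk, nu = _table_args()
        deadline = -1.0 if config.deadline_s is None else float(config.deadline_s)
        c1, s2, trans, c2, rew, rt1, rt2, _, _, _ = K.simulate_ddm(
            walk, blocks, config.p_common,
            params.alpha1, params.alpha2, params.lam, params.w, params.p,
            params.b1, params.a1, params.tau1,
            params.b2, params.a2, params.tau2,
            deadline, tab, dk, du, umax, nk, nu, agent_seed)
    else:
        raise TypeError("params must be RLParams or DDMRLParams")

    trials = pd.DataFrame({
        "block": blocks + 1,
        "trial": np.arange(1, config.n_trials + 1),
        "choice1": c1.astype(int) + 1,
        "transition": np.where(trans == 0, "common", "rare"),
        "state2": s2.astype(int) + 2,
        "choice2": c2.astype(int) + 1,
        "reward": rew.astype(int),
        "rt1": rt1,
        "rt2": rt2,
    })
    return SessionData(subject_id, timepoint, config, trials)


def pack_session(session: SessionData) -> dict:
    """0-based integer arrays for the numba kernels.

    ``new_block`` marks trials where the perseveration memory resets: the
    first retained trial of each block.
    """
    t = session.trials
    block = t["block"].to_numpy(dtype=np.int64)
    new_block = np.ones(len(t), dtype=np.bool_)
    if len(t):
        new_block[1:] = block[1:] != block[:-1]
        new_block[0] = True
    return {
        "choice1": t["choice1"].to_numpy(dtype=np.int8) - 1,
        "state2": t["state2"].to_numpy(dtype=np.int8) - 2,
        "transition": (t["transition"].to_numpy() == "rare").astype(np.int8),
        "choice2": t["choice2"].to_numpy(dtype=np.int8) - 1,
        "reward": t["reward"].to_numpy(dtype=np.int8),
        "rt1": t["rt1"].to_numpy(dtype=float),
        "rt2": t["rt2"].to_numpy(dtype=float),
        "trial": t["trial"].to_numpy(dtype=np.int64),
        "block": block,
        "new_block": new_block,
        "p_common": float(session.config.p_common),
    }
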