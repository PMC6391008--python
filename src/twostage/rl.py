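"""Hybrid model-based / model-free value recursion and the choice likelihood.

Model-free values are cached by SARSA prediction errors with all Q-values
initialised to zero at session start: the chosen second-stage bandit moves
toward the reward by ``alpha2 * (r - Q_mf(a2))``, and the chosen first-stage
action by ``alpha1 * (Q_mf(a2) - Q_mf(a1)) + alpha1 * lam * (r - Q_mf(a2))``
using the second-stage value *before* its own update (both prediction errors
are computed from pre-update values, then committed).  Model-based values
look forward through the known transition probabilities to the best bandit
in each second-stage state.  First-stage net values blend the two systems
with the weight ``w`` and add a perseveration bonus ``p`` for the previous
trial's action (no bonus on the first trial of a block).  The choice-only
likelihood scores stage-1 choices by a softmax over the net values (inverse
temperature ``beta1``) and stage-2 choices by a softmax over the model-free
values within the visited state (``beta2``).

The functions here are a plain-numpy trajectory implementation used for
inspection and as the reference for the compiled likelihood kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .params import RLParams
from .task import SessionData, pack_session

__all__ = [
    "LatentTrajectory",
    "update_values",
    "model_based_values",
    "net_values",
    "latent_trajectory",
    "choice_loglik",
]


@dataclass
class LatentTrajectory:
    """Per-trial latent values, evaluated *before* that trial's update.

    ``q_mf2`` has shape (n, 2, 2) indexed (trial, state, bandit); ``q_mf1``,
    ``q_mb`` and ``q_net`` have shape (n, 2); ``stay`` holds the previous
    first-stage action (0/1) or -1 on the first trial of a block.
    ``logp1``/``logp2`` are the per-trial log-probabilities of the observed
    choices (filled by :func:`latent_trajectory` when params are supplied).
    """

    q_mf1: np.ndarray
    q_mf2: np.ndarray
    q_mb: np.ndarray
    q_net: np.ndarray
    stay: np.ndarray
    logp1: np.ndarray
    logp2: np.ndarray


def update_values(q_mf1: np.ndarray, q_mf2: np.ndarray,
                  choice1: int, state2: int, choice2: int, reward: float,
                  params: RLParams) -> tuple[np.ndarray, np.ndarray]:
    """One trial's SARSA update (0-based indices); returns new copies.

    The first-stage update uses the pre-update second-stage value; unchosen
    values are untouched.
    """
    q1 = q_mf1.copy()
    q2 = q_mf2.copy()
    q2v = q2[state2, choice2]
    q1[choice1] += params.alpha1 * (q2v - q1[choice1]) \
        + params.alpha1 * params.lam * (reward - q2v)
    q2[state2, choice2] += params.alpha2 * (reward - q2v)
    return q1, q2


def model_based_values(q_mf2: np.ndarray, p_common: float = 0.7) -> np.ndarray:
    """Prospective first-stage values from the best bandit per state.

    ``Q_mb(a) = P(s_a|a) max Q_mf(s_a) + P(s_other|a) max Q_mf(s_other)``
    with the transition probabilities treated as known constants.
    """
    m = q_mf2.max(axis=1)
    return np.array([p_common * m[0] + (1 - p_common) * m[1],
                     (1 - p_common) * m[0] + p_common * m[1]])


def net_values(q_mf1: np.ndarray, q_mb: np.ndarray, prev_choice1: int,
               params: RLParams) -> np.ndarray:
    """Blend the two systems and add the perseveration bonus.

    ``prev_choice1`` is the 0-based previous first-stage action, or -1 on a
    block's first trial (no bonus for either action).
    """
    q = (1 - params.w) * q_mf1 + params.w * q_mb
    if prev_choice1 >= 0:
        q = q.copy()
        q[prev_choice1] += params.p
    return q


def _log_softmax(x: np.ndarray) -> np.ndarray:
    m = x.max()
    return x - m - np.log(np.exp(x - m).sum())


def latent_trajectory(params: RLParams, session: SessionData) -> LatentTrajectory:
    """Roll the value recursion through a session, recording every latent."""
    arr = pack_session(session)
    n = arr["choice1"].size
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    out = LatentTrajectory(
        q_mf1=np.zeros((n, 2)), q_mf2=np.zeros((n, 2, 2)),
        q_mb=np.zeros((n, 2)), q_net=np.zeros((n, 2)),
        stay=np.zeros(n, dtype=int), logp1=np.zeros(n), logp2=np.zeros(n))
    prev = -1
    for t in range(n):
        if arr["new_block"][t]:
            prev = -1
        qmb = model_based_values(q2, arr["p_common"])
        qnet = net_values(q1, qmb, prev, params)
        out.q_mf1[t] = q1
        out.q_mf2[t] = q2
        out.q_mb[t] = qmb
        out.q_net[t] = qnet
        out.stay[t] = prev
        c1, s, c2 = arr["choice1"][t], arr["state2"][t], arr["choice2"][t]
        out.logp1[t] = _log_softmax(params.beta1 * qnet)[c1]
        out.logp2[t] = _log_softmax(params.beta2 * q2[s])[c2]
        q1, q2 = update_values(q1, q2, c1, s, c2, arr["reward"][t], params)
        prev = c1
    return out


def choice_loglik(params: RLParams, session: SessionData) -> float:
    """Summed log-likelihood of all observed stage-1 and stage-2 choices."""
    th = params.as_array()
    if not np.all(np.isfinite(th)):
        raise ValueError("non-finite parameters")
    arr = pack_session(session)
    if arr["choice1"].size == 0:
        raise ValueError("empty session")
    return float(K.rl_loglik(
        *th,
        arr["choice1"], arr["state2"], arr["choice2"], arr["reward"],
        arr["new_block"], arr["p_common"]))
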