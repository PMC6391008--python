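"""Numba-compiled computational kernels.

Everything in this module is a plain function of scalars and ndarrays so it
can be JIT-compiled.  Public, documented entry points live in the sibling
modules (:mod:`twostage.ddm`, :mod:`twostage.task`, ...); these kernels are
implementation detail and their signatures may change.

Conventions used throughout:

* first-stage actions and second-stage choices are 0-based (0/1),
* second-stage states are 0-based (0/1); action ``i`` leads to state ``i``
  on a common transition,
* the four bandits are indexed ``2*state + choice2``,
* ``transition``: 0 = common, 1 = rare,
* the diffusion noise SD is fixed at 1 and the accumulator starts midway
  between the boundaries.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

PI = math.pi

# ---------------------------------------------------------------------------
# Wiener first-passage-time density (small-time / large-time series)
# ---------------------------------------------------------------------------


@njit(cache=True)
def wfpt_lower(t, v, a, w, err):
    """Density of first passage through the LOWER boundary at time ``t``.

    Drift ``v``, boundary separation ``a``, relative start ``w`` (fraction of
    ``a``), unit diffusion coefficient.  ``err`` is the absolute truncation
    tolerance of the (normalised) infinite series; the expansion (small-time
    vs large-time) requiring fewer terms is selected per evaluation.
    """
    if t <= 0.0:
        return 0.0
    tt = t / (a * a)  # normalised time

    # number of terms needed by the large-time expansion
    if PI * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(PI * tt * err) / (PI * PI * tt))
        kl = max(kl, 1.0 / (PI * math.sqrt(tt)))
    else:
        kl = 1.0 / (PI * math.sqrt(tt))
    # number of terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * PI * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * math.sqrt(2.0 * PI * tt) * err))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0

    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            z = w + 2.0 * k
            p += z * math.exp(-z * z / (2.0 * tt))
        p /= math.sqrt(2.0 * PI * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * PI * PI * tt / 2.0) * math.sin(k * PI * w)
        p *= PI

    if p < 0.0:  # truncation can ring slightly negative
        p = 0.0
    return p * math.exp(-v * a * w - v * v * t / 2.0) / (a * a)


@njit(cache=True)
def wfpt_logdensity(t, v, a, w, err, floor):
    d = wfpt_lower(t, v, a, w, err)
    if d < floor:
        d = floor
    return math.log(d)


# ---------------------------------------------------------------------------
# Fast first-passage sampling via a precomputed conditional quantile table
# ---------------------------------------------------------------------------
#
# With the start point fixed midway (w = 1/2) the first-passage time is
# conditionally independent of which boundary is reached: both conditional
# time densities are proportional to exp(-v^2 t / 2) * g(t; a) with the same
# g.  In normalised time t' = t / a^2 the conditional law depends only on
# kappa = |a * v|.  The table stores, for a grid of kappa, the quantile
# function of t' evaluated on a uniform grid of probabilities; beyond the
# last tabulated quantile the (asymptotically exact) exponential tail with
# rate (kappa^2 + pi^2)/2 is used.


@njit(cache=True)
def sample_fpt_norm(kappa, qtab, dk, du, umax, nk, nu):
    """Sample a normalised (a=1) first-passage time at given |kappa|."""
    if kappa < 0.0:
        kappa = -kappa
    kmax = dk * (nk - 1)
    if kappa > kmax:
        kappa = kmax
    fi = kappa / dk
    i0 = int(fi)
    if i0 >= nk - 1:
        i0 = nk - 2
    fk = fi - i0

    u = np.random.random()
    if u >= umax:
        # exponential tail beyond the last tabulated quantile
        q0 = qtab[i0, nu - 1] * (1.0 - fk) + qtab[i0 + 1, nu - 1] * fk
        rate = (kappa * kappa + PI * PI) / 2.0
        return q0 + np.random.exponential(1.0 / rate)
    fj = u / du
    j0 = int(fj)
    if j0 >= nu - 1:
        j0 = nu - 2
    fu = fj - j0
    q00 = qtab[i0, j0]
    q01 = qtab[i0, j0 + 1]
    q10 = qtab[i0 + 1, j0]
    q11 = qtab[i0 + 1, j0 + 1]
    return (q00 * (1.0 - fu) + q01 * fu) * (1.0 - fk) + (q10 * (1.0 - fu) + q11 * fu) * fk


@njit(cache=True)
def sample_ddm(a, drift, qtab, dk, du, umax, nk, nu):
    """One diffusion decision: returns (choice, decision_time).

    ``drift`` is signed toward option 0; choice 0 is returned with the exact
    absorption probability 1/(1+exp(-a*drift)).
    """
    kappa = a * drift
    p0 = 1.0 / (1.0 + math.exp(-kappa))
    c = 0 if np.random.random() < p0 else 1
    tnorm = sample_fpt_norm(abs(kappa), qtab, dk, du, umax, nk, nu)
    return c, a * a * tnorm


@njit(cache=True)
def fill_conditional_density(kappas, tgrid, err):
    """Conditional (on boundary) normalised FPT density, one row per kappa."""
    out = np.empty((kappas.shape[0], tgrid.shape[0]))
    for i in range(kappas.shape[0]):
        k = kappas[i]
        pup = 1.0 / (1.0 + math.exp(-k))
        for j in range(tgrid.shape[0]):
            # upper-boundary density at drift +kappa == lower at drift -kappa
            out[i, j] = wfpt_lower(tgrid[j], -k, 1.0, 0.5, err) / pup
    return out


# ---------------------------------------------------------------------------
# Brute-force Euler-Maruyama first-passage sampler (reference oracle)
# ---------------------------------------------------------------------------


@njit(cache=True)
def euler_fpt(a, v, w, dt, n, seed):
    """Simulate ``n`` first passages by the Euler scheme with a Brownian-bridge
    crossing correction between grid points (removes the leading-order
    boundary-overshoot bias).  Returns (boundary 1=upper/0=lower, time)."""
    np.random.seed(seed)
    bnd = np.empty(n, np.int8)
    tim = np.empty(n)
    sq = math.sqrt(dt)
    near = 20.0 * dt  # bridge crossing negligible beyond exp(-40)
    for i in range(n):
        x = w * a
        t = 0.0
        while True:
            xn = x + v * dt + sq * np.random.standard_normal()
            t += dt
            if xn >= a:
                b = 1
                break
            if xn <= 0.0:
                b = 0
                break
            pu = (math.exp(-2.0 * (a - x) * (a - xn) / dt)
                  if (a - x) * (a - xn) < near else 0.0)
            pl = math.exp(-2.0 * x * xn / dt) if x * xn < near else 0.0
            if pu > 0.0 or pl > 0.0:
                u = np.random.random()
                if u < pu:
                    b = 1
                    break
                elif u < pu + pl:
                    b = 0
                    break
            x = xn
        bnd[i] = b
        tim[i] = t - 0.5 * dt
    return bnd, tim


# ---------------------------------------------------------------------------
# Reward random walks
# ---------------------------------------------------------------------------


@njit(cache=True)
def gen_walk_ns(n_trials, sd, lo, hi):
    """Four independent Gaussian random walks reflected at [lo, hi].

    Uses the current state of numba's thread-local RNG (callers seed)."""
    probs = np.empty((4, n_trials))
    for b in range(4):
        x = lo + (hi - lo) * np.random.random()
        for t in range(n_trials):
            probs[b, t] = x
            if t < n_trials - 1:
                x += sd * np.random.standard_normal()
                while x < lo or x > hi:
                    if x < lo:
                        x = 2.0 * lo - x
                    else:
                        x = 2.0 * hi - x
    return probs


@njit(cache=True)
def gen_walk(n_trials, sd, lo, hi, seed):
    np.random.seed(seed)
    return gen_walk_ns(n_trials, sd, lo, hi)


# ---------------------------------------------------------------------------
# Closed-loop agent simulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def simulate_rl_ns(walk, block_id, p_common,
                   alpha1, alpha2, beta1, beta2, lam, w, p):
    """Softmax (choice-only) hybrid agent; returns trial arrays."""
    n = walk.shape[1]
    choice1 = np.empty(n, np.int8)
    state2 = np.empty(n, np.int8)
    transition = np.empty(n, np.int8)
    choice2 = np.empty(n, np.int8)
    reward = np.empty(n, np.int8)
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    for t in range(n):
        if t > 0 and block_id[t] != block_id[t - 1]:
            prev = -1
        m0 = max(q2[0, 0], q2[0, 1])
        m1 = max(q2[1, 0], q2[1, 1])
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = (1.0 - p_common) * m0 + p_common * m1
        qn0 = (1.0 - w) * q1[0] + w * qmb0 + (p if prev == 0 else 0.0)
        qn1 = (1.0 - w) * q1[1] + w * qmb1 + (p if prev == 1 else 0.0)
        # stage-1 softmax
        x0 = beta1 * qn0
        x1 = beta1 * qn1
        m = max(x0, x1)
        p0 = math.exp(x0 - m) / (math.exp(x0 - m) + math.exp(x1 - m))
        c1 = 0 if np.random.random() < p0 else 1
        common = np.random.random() < p_common
        s = c1 if common else 1 - c1
        y0 = beta2 * q2[s, 0]
        y1 = beta2 * q2[s, 1]
        m = max(y0, y1)
        ps0 = math.exp(y0 - m) / (math.exp(y0 - m) + math.exp(y1 - m))
        c2 = 0 if np.random.random() < ps0 else 1
        r = 1 if np.random.random() < walk[2 * s + c2, t] else 0
        q2v = q2[s, c2]
        q1[c1] += alpha1 * (q2v - q1[c1]) + alpha1 * lam * (r - q2v)
        q2[s, c2] += alpha2 * (r - q2v)
        prev = c1
        choice1[t] = c1
        state2[t] = s
        transition[t] = 0 if common else 1
        choice2[t] = c2
        reward[t] = r
    return choice1, state2, transition, choice2, reward


@njit(cache=True)
def simulate_rl(walk, block_id, p_common,
                alpha1, alpha2, beta1, beta2, lam, w, p, seed):
    np.random.seed(seed)
    return simulate_rl_ns(walk, block_id, p_common,
                          alpha1, alpha2, beta1, beta2, lam, w, p)


@njit(cache=True)
def simulate_ddm_ns(walk, block_id, p_common,
                    alpha1, alpha2, lam, w, p,
                    b1, a1, tau1, b2, a2, tau2,
                    deadline, qtab, dk, du, umax, nk, nu):
    """Diffusion (choice + RT) hybrid agent.

    Also emits, per trial, the pre-update within-state Q spreads (max-min of
    the two bandit values) for both second-stage states and which state holds
    the globally maximal bandit value; these drive the mechanism analyses.
    ``deadline`` < 0 disables the response deadline, otherwise stage samples
    whose RT exceeds it are redrawn (up to 100 attempts).
    """
    n = walk.shape[1]
    choice1 = np.empty(n, np.int8)
    state2 = np.empty(n, np.int8)
    transition = np.empty(n, np.int8)
    choice2 = np.empty(n, np.int8)
    reward = np.empty(n, np.int8)
    rt1 = np.empty(n)
    rt2 = np.empty(n)
    dq0 = np.empty(n)
    dq1 = np.empty(n)
    best = np.empty(n, np.int8)
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    for t in range(n):
        if t > 0 and block_id[t] != block_id[t - 1]:
            prev = -1
        m0 = max(q2[0, 0], q2[0, 1])
        m1 = max(q2[1, 0], q2[1, 1])
        dq0[t] = abs(q2[0, 0] - q2[0, 1])
        dq1[t] = abs(q2[1, 0] - q2[1, 1])
        best[t] = 0 if m0 >= m1 else 1
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = (1.0 - p_common) * m0 + p_common * m1
        qn0 = (1.0 - w) * q1[0] + w * qmb0 + (p if prev == 0 else 0.0)
        qn1 = (1.0 - w) * q1[1] + w * qmb1 + (p if prev == 1 else 0.0)
        d1 = b1 * (qn0 - qn1)
        c1, dt1 = sample_ddm(a1, d1, qtab, dk, du, umax, nk, nu)
        if deadline > 0.0:
            tries = 0
            while dt1 + tau1 > deadline and tries < 100:
                c1, dt1 = sample_ddm(a1, d1, qtab, dk, du, umax, nk, nu)
                tries += 1
        common = np.random.random() < p_common
        s = c1 if common else 1 - c1
        d2 = b2 * (q2[s, 0] - q2[s, 1])
        c2, dt2 = sample_ddm(a2, d2, qtab, dk, du, umax, nk, nu)
        if deadline > 0.0:
            tries = 0
            while dt2 + tau2 > deadline and tries < 100:
                c2, dt2 = sample_ddm(a2, d2, qtab, dk, du, umax, nk, nu)
                tries += 1
        r = 1 if np.random.random() < walk[2 * s + c2, t] else 0
        q2v = q2[s, c2]
        q1[c1] += alpha1 * (q2v - q1[c1]) + alpha1 * lam * (r - q2v)
        q2[s, c2] += alpha2 * (r - q2v)
        prev = c1
        choice1[t] = c1
        state2[t] = s
        transition[t] = 0 if common else 1
        choice2[t] = c2
        reward[t] = r
        rt1[t] = dt1 + tau1
        rt2[t] = dt2 + tau2
    return choice1, state2, transition, choice2, reward, rt1, rt2, dq0, dq1, best


@njit(cache=True)
def simulate_ddm(walk, block_id, p_common,
                 alpha1, alpha2, lam, w, p,
                 b1, a1, tau1, b2, a2, tau2,
                 deadline, qtab, dk, du, umax, nk, nu, seed):
    np.random.seed(seed)
    return simulate_ddm_ns(walk, block_id, p_common,
                           alpha1, alpha2, lam, w, p,
                           b1, a1, tau1, b2, a2, tau2,
                           deadline, qtab, dk, du, umax, nk, nu)


# ---------------------------------------------------------------------------
# Likelihood kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def rl_loglik(alpha1, alpha2, beta1, beta2, lam, w, p,
              choice1, state2, choice2, reward, new_block, p_common):
    """Joint log-likelihood of stage-1 and stage-2 choices (softmax)."""
    n = choice1.shape[0]
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    ll = 0.0
    for t in range(n):
        if new_block[t]:
            prev = -1
        m0 = max(q2[0, 0], q2[0, 1])
        m1 = max(q2[1, 0], q2[1, 1])
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = (1.0 - p_common) * m0 + p_common * m1
        qn0 = (1.0 - w) * q1[0] + w * qmb0 + (p if prev == 0 else 0.0)
        qn1 = (1.0 - w) * q1[1] + w * qmb1 + (p if prev == 1 else 0.0)
        c1 = choice1[t]
        x0 = beta1 * qn0
        x1 = beta1 * qn1
        m = max(x0, x1)
        lse = m + math.log(math.exp(x0 - m) + math.exp(x1 - m))
        ll += (x0 if c1 == 0 else x1) - lse
        s = state2[t]
        c2 = choice2[t]
        y0 = beta2 * q2[s, 0]
        y1 = beta2 * q2[s, 1]
        m = max(y0, y1)
        lse = m + math.log(math.exp(y0 - m) + math.exp(y1 - m))
        ll += (y0 if c2 == 0 else y1) - lse
        r = reward[t]
        q2v = q2[s, c2]
        q1[c1] += alpha1 * (q2v - q1[c1]) + alpha1 * lam * (r - q2v)
        q2[s, c2] += alpha2 * (r - q2v)
        prev = c1
    return ll


@njit(cache=True)
def ddm_loglik(alpha1, alpha2, lam, w, p, b1, a1, tau1, b2, a2, tau2,
               choice1, state2, choice2, reward, rt1, rt2,
               new_block, p_common, err, floor):
    """Joint log-likelihood of (choice, RT) at both stages.

    Per trial and stage the drift is the scaled Q difference of the chosen
    minus the unchosen option and the chosen option sits at the upper
    boundary; the density is evaluated at rt - tau.  Densities below
    ``floor`` (including rt <= tau) contribute log(floor).
    """
    n = choice1.shape[0]
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    ll = 0.0
    for t in range(n):
        if new_block[t]:
            prev = -1
        m0 = max(q2[0, 0], q2[0, 1])
        m1 = max(q2[1, 0], q2[1, 1])
        qmb0 = p_common * m0 + (1.0 - p_common) * m1
        qmb1 = (1.0 - p_common) * m0 + p_common * m1
        qn0 = (1.0 - w) * q1[0] + w * qmb0 + (p if prev == 0 else 0.0)
        qn1 = (1.0 - w) * q1[1] + w * qmb1 + (p if prev == 1 else 0.0)
        c1 = choice1[t]
        # drift toward the chosen option; chosen = upper boundary
        d1 = b1 * ((qn0 - qn1) if c1 == 0 else (qn1 - qn0))
        td = rt1[t] - tau1
        if td > 0.0:
            ll += wfpt_logdensity(td, -d1, a1, 0.5, err, floor)
        else:
            ll += math.log(floor)
        s = state2[t]
        c2 = choice2[t]
        d2 = b2 * ((q2[s, 0] - q2[s, 1]) if c2 == 0 else (q2[s, 1] - q2[s, 0]))
        td = rt2[t] - tau2
        if td > 0.0:
            ll += wfpt_logdensity(td, -d2, a2, 0.5, err, floor)
        else:
            ll += math.log(floor)
        r = reward[t]
        q2v = q2[s, c2]
        q1[c1] += alpha1 * (q2v - q1[c1]) + alpha1 * lam * (r - q2v)
        q2[s, c2] += alpha2 * (r - q2v)
        prev = c1
    return ll


# ---------------------------------------------------------------------------
# Fast model-agnostic scoring
# ---------------------------------------------------------------------------


@njit(cache=True)
def score_cells(choice1, transition, reward, rt2, trial_idx, block_id,
                mask_stay, mask_rt):
    """Stay-cell tallies and RT-by-transition tallies for one session.

    Returns (stay_sum[4], stay_n[4], rt_sum[2], rt_n[2]) with cells ordered
    (common-rew, common-unrew, rare-rew, rare-unrew) and rt bins
    (common, rare).  A stay pair (t-1, t) counts only when the two trials are
    consecutive within the same block and ``mask_stay[t]``; trial t's RT
    counts when ``mask_rt[t]`` and rt2 is finite.
    """
    stay_sum = np.zeros(4)
    stay_n = np.zeros(4)
    rt_sum = np.zeros(2)
    rt_n = np.zeros(2)
    n = choice1.shape[0]
    for t in range(n):
        if mask_rt[t] and np.isfinite(rt2[t]):
            k = transition[t]
            rt_sum[k] += rt2[t]
            rt_n[k] += 1.0
        if t == 0 or not mask_stay[t]:
            continue
        if block_id[t] != block_id[t - 1] or trial_idx[t] != trial_idx[t - 1] + 1:
            continue
        cell = 2 * transition[t - 1] + (1 - reward[t - 1])
        stay_sum[cell] += 1.0 if choice1[t] == choice1[t - 1] else 0.0
        stay_n[cell] += 1.0
    return stay_sum, stay_n, rt_sum, rt_n


# ---------------------------------------------------------------------------
# Whole-cohort simulation + scoring (hot path of the power analysis)
# ---------------------------------------------------------------------------


@njit(cache=True)
def ddm_cohort_scores(ws, n_trials, block_id, p_common, walk_sd, lo, hi,
                      nui_lo, nui_hi, qtab, dk, du, umax, nk, nu, seed):
    """Simulate one agent per entry of ``ws`` and return (MB-I, MB-II) rows.

    Nuisance parameters (alpha1, alpha2, lam, p, b1, a1, tau1, b2, a2, tau2)
    are drawn uniformly from [nui_lo, nui_hi] per agent; each agent gets a
    fresh reward walk.  Rows are NaN where a score is undefined.
    """
    np.random.seed(seed)
    n_agents = ws.shape[0]
    out = np.empty((n_agents, 2))
    mask = np.ones(n_trials, np.bool_)
    trial_idx = np.arange(n_trials)
    for i in range(n_agents):
        r = np.empty(10)
        for j in range(10):
            r[j] = nui_lo[j] + (nui_hi[j] - nui_lo[j]) * np.random.random()
        walk = gen_walk_ns(n_trials, walk_sd, lo, hi)
        c1, s2, tr, c2, rew, rt1, rt2, dq0, dq1, best = simulate_ddm_ns(
            walk, block_id, p_common,
            r[0], r[1], r[2], ws[i], r[3],
            r[4], r[5], r[6], r[7], r[8], r[9],
            -1.0, qtab, dk, du, umax, nk, nu)
        ssum, sn, rsum, rn = score_cells(c1, tr, rew, rt2, trial_idx,
                                         block_id, mask, mask)
        if sn[0] > 0 and sn[1] > 0 and sn[2] > 0 and sn[3] > 0:
            out[i, 0] = (ssum[0] / sn[0] - ssum[2] / sn[2]) \
                - (ssum[1] / sn[1] - ssum[3] / sn[3])
        else:
            out[i, 0] = np.nan
        if rn[0] > 0 and rn[1] > 0:
            out[i, 1] = rsum[1] / rn[1] - rsum[0] / rn[0]
        else:
            out[i, 1] = np.nan
    return out
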