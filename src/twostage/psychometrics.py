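"""Simulation studies: recovery, reliability, mechanism sweep, power.

These reproduce, on synthetic cohorts, the psychometric properties of the
two model-basedness measurement routes:

* **parameter recovery** - simulate agents with known parameters, refit,
  and rank-correlate true vs recovered values per parameter;
* **split-half reliability** - score odd and even trials separately
  (halving by the *outcome* trial's parity while keeping the previous
  trial's conditioning regardless of its parity), correlate across
  subjects and apply the Spearman-Brown step-up 2r/(1+r);
* **w-sweep mechanism analysis** - sweep the model-based weight and track
  how the within-state second-stage value spread (max - min Q) and both
  model-agnostic scores respond;
* **power analysis** - two groups whose w means differ by a small, medium
  or large effect; per iteration simulate every agent, compute (MB-I,
  MB-II) and test the group difference with a two-group MANOVA (Wilks'
  lambda, Bartlett chi-square approximation, df = number of scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels as K
from .ddm import _table_args
from .fitting import FitOptions, fit_individual
from .params import DDMRLParams, RLParams
from .scores import mb1_choice
from .task import SessionData, TaskConfig, block_ids, simulate_agent

__all__ = [
    "RecoveryConfig", "RecoveryResult", "parameter_recovery",
    "ReliabilityReport", "split_half", "reliability_curve",
    "CorrelationResult", "temporal_stability",
    "SweepResult", "w_sweep", "simulate_cohort",
    "PowerConfig", "PowerResult", "power_analysis", "manova_chi2",
    "spearman_brown", "UNIFORM_RANGES",
]

#: canonical uniform sampling ranges for agent parameters
UNIFORM_RANGES = {
    "alpha1": (0.0, 1.0), "alpha2": (0.0, 1.0),
    "beta1": (1.0, 8.0), "beta2": (1.0, 8.0),
    "lam": (0.0, 1.0), "w": (0.0, 1.0), "p": (0.0, 0.5),
    "b1": (1.0, 10.0), "a1": (1.0, 3.0), "tau1": (0.01, 0.5),
    "b2": (1.0, 10.0), "a2": (1.0, 3.0), "tau2": (0.01, 0.5),
}

_NUISANCE = ["alpha1", "alpha2", "lam", "p",
             "b1", "a1", "tau1", "b2", "a2", "tau2"]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def spearman_brown(r: float) -> float:
    """Step the half-test correlation up to full-length reliability."""
    return 2.0 * r / (1.0 + r)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryConfig:
    model: str = "ddm11"          # 'rl7' or 'ddm11' (aliases 'rl', 'ddmrl')
    n_agents: int = 100
    n_trials: int = 200
    ranges: dict = field(default_factory=dict)   # overrides of UNIFORM_RANGES
    seed: int = 0
    fit_options: Optional[FitOptions] = None

    def resolved_model(self) -> str:
        return {"rl": "rl7", "ddmrl": "ddm11"}.get(self.model, self.model)


@dataclass
class RecoveryResult:
    correlations: dict            # parameter -> Spearman r(true, recovered)
    true: pd.DataFrame
    recovered: pd.DataFrame
    n_failures: int


def parameter_recovery(config: RecoveryConfig,
                       task: Optional[TaskConfig] = None) -> RecoveryResult:
    """Simulate agents with uniformly drawn parameters, refit, correlate.

    Fit bounds are set to the sampling ranges.  Agents whose fit failed are
    excluded from the correlations and counted.
    """
    from .fitting import MODELS
    model = config.resolved_model()
    names = MODELS[model]
    ranges = {**UNIFORM_RANGES, **config.ranges}
    task = task or TaskConfig(n_trials=config.n_trials)
    rng = np.random.default_rng(config.seed)
    seeds = _child_seeds(config.seed + 1, config.n_agents)
    opts = config.fit_options or FitOptions(seed=config.seed)

    rows_true, rows_est, n_fail = [], [], 0
    for i in range(config.n_agents):
        theta = {n: rng.uniform(*ranges[n]) for n in names}
        params = (RLParams(**theta) if model == "rl7"
                  else DDMRLParams(**theta))
        sess = simulate_agent(params, task, int(seeds[i]),
                              subject_id=f"agent{i:03d}")
        fit = fit_individual(model, sess,
                             FitOptions(**{**opts.__dict__,
                                           "seed": opts.seed + i}),
                             bounds=[ranges[n] for n in names])
        if not fit.converged:
            n_fail += 1
            continue
        rows_true.append(theta)
        rows_est.append(dict(zip(names, fit.estimates)))
    true = pd.DataFrame(rows_true)
    est = pd.DataFrame(rows_est)
    corr = {n: float(stats.spearmanr(true[n], est[n]).statistic)
            for n in names}
    return RecoveryResult(corr, true, est, n_fail)


# ---------------------------------------------------------------------------
# Split-half reliability
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityReport:
    score_name: str
    r_raw: float
    r_corrected: float
    n_subjects: int
    n_trials: int
    n_dropped: int


def _parity_masks(session: SessionData):
    tr = session.trials["trial"].to_numpy()
    odd = (tr % 2) == 1
    return odd, ~odd


def split_half(sessions: Sequence[SessionData],
               score_fn: Callable[..., float] = mb1_choice,
               correction: bool = True) -> ReliabilityReport:
    """Odd/even split-half reliability of a per-session score.

    Halves are defined by the parity of the outcome trial (the stay trial
    for MB-I, the RT trial for MB-II); the previous trial's conditioning
    stays in the analysis regardless of its own parity.  Subjects with an
    undefined half-score are dropped pairwise and counted.
    """
    a, b = [], []
    dropped = 0
    for s in sessions:
        odd, even = _parity_masks(s)
        x, y = score_fn(s, odd), score_fn(s, even)
        if np.isfinite(x) and np.isfinite(y):
            a.append(x)
            b.append(y)
        else:
            dropped += 1
    if len(a) < 3:
        raise ValueError("need at least 3 subjects with defined half-scores")
    r = float(stats.pearsonr(a, b).statistic)
    return ReliabilityReport(
        score_name=getattr(score_fn, "__name__", "score"),
        r_raw=r, r_corrected=spearman_brown(r) if correction else r,
        n_subjects=len(a),
        n_trials=max(s.n_trials for s in sessions),
        n_dropped=dropped)


def reliability_curve(sessions: Sequence[SessionData],
                      score_fn: Callable[..., float] = mb1_choice,
                      trial_grid: Optional[Sequence[int]] = None,
                      ) -> pd.DataFrame:
    """Split-half reliability recomputed on the first-n-trials truncations.

    Default grid: every trial count from 20 to the shortest session.
    """
    n_max = min(s.n_trials for s in sessions)
    grid = list(trial_grid) if trial_grid is not None else list(
        range(20, n_max + 1))
    if any(m > n_max or m < 2 for m in grid):
        raise ValueError("trial_grid outside session length")
    rows = []
    for m in grid:
        trunc = [s.truncate(m) for s in sessions]
        rep = split_half(trunc, score_fn)
        rows.append({"n_trials": m, "r_raw": rep.r_raw,
                     "r_corrected": rep.r_corrected,
                     "n_subjects": rep.n_subjects,
                     "n_dropped": rep.n_dropped})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Temporal stability
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    method: str
    defined: bool = True


def _fisher_ci(r: float, n: int, n_partialled: int = 0):
    if n - 3 - n_partialled <= 0 or abs(r) >= 1:
        return float("nan"), float("nan")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3 - n_partialled)
    return float(np.tanh(z - 1.959964 * se)), float(np.tanh(z + 1.959964 * se))


def temporal_stability(scores_t1: Sequence[float], scores_t2: Sequence[float],
                       method: str = "pearson",
                       covariate: Optional[Sequence[float]] = None,
                       ) -> CorrelationResult:
    """Correlation of a subject-level score between two sessions.

    ``method='partial'`` computes the Spearman partial correlation given
    ``covariate`` (correlation of the rank residuals).  A constant input
    yields an undefined (flagged) result rather than an error.
    """
    x = np.asarray(scores_t1, dtype=float)
    y = np.asarray(scores_t2, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if covariate is not None:
        z = np.asarray(covariate, dtype=float)
        ok &= np.isfinite(z)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"),
                                 n, method, defined=False)
    npart = 0
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    elif method == "partial":
        if covariate is None:
            raise ValueError("partial correlation needs a covariate")
        z = np.asarray(covariate, dtype=float)[ok]
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        rxy = np.corrcoef(rx, ry)[0, 1]
        rxz = np.corrcoef(rx, rz)[0, 1]
        ryz = np.corrcoef(ry, rz)[0, 1]
        den = np.sqrt((1 - rxz**2) * (1 - ryz**2))
        if den == 0:
            return CorrelationResult(float("nan"), float("nan"),
                                     float("nan"), n, method, defined=False)
        r = float((rxy - rxz * ryz) / den)
        npart = 1
    else:
        raise ValueError("method must be pearson, spearman or partial")
    lo, hi = _fisher_ci(r, n, npart)
    return CorrelationResult(r, lo, hi, n, method)


# ---------------------------------------------------------------------------
# Cohort simulation helper
# ---------------------------------------------------------------------------


def simulate_cohort(model: str, n_agents: int, n_trials: int, seed: int,
                    ranges: Optional[dict] = None,
                    task: Optional[TaskConfig] = None,
                    timepoint: str = "t1") -> list[SessionData]:
    """Cohort with per-agent parameters drawn from the uniform ranges."""
    from .fitting import MODELS
    model = {"rl": "rl7", "ddmrl": "ddm11"}.get(model, model)
    names = MODELS[model]
    rng = np.random.default_rng(seed)
    seeds = _child_seeds(seed + 1, n_agents)
    rr = {**UNIFORM_RANGES, **(ranges or {})}
    task = task or TaskConfig(n_trials=n_trials)
    out = []
    for i in range(n_agents):
        theta = {n: rng.uniform(*rr[n]) for n in names}
        params = RLParams(**theta) if model == "rl7" else DDMRLParams(**theta)
        out.append(simulate_agent(params, task, int(seeds[i]),
                                  subject_id=f"agent{i:03d}",
                                  timepoint=timepoint))
    return out


# ---------------------------------------------------------------------------
# w-sweep mechanism analysis
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    per_w: pd.DataFrame         # one row per w level (means over experiments)
    dq_best_mean: float         # mean within-state spread, best state
    dq_worst_mean: float        # ... state not holding the global max
    n_experiments: int
    n_trials: int


def w_sweep(w_grid: Sequence[float] = tuple(np.round(np.arange(0, 1.01, .1), 2)),
            n_experiments: int = 200, n_trials: int = 5000, seed: int = 0,
            task: Optional[TaskConfig] = None,
            ranges: Optional[dict] = None) -> SweepResult:
    """Sweep the model-based weight and measure its behavioural signatures.

    Per w level, ``n_experiments`` diffusion agents (other parameters
    uniform in the canonical ranges) each run ``n_trials`` trials.  Per
    trial the within-state Q spread (max - min of the two bandit values,
    pre-update) is recorded for the visited state split by transition, and
    for the state holding / not holding the globally maximal bandit value;
    also whether the best state was reached via a common transition.
    Standardised mean MB-I / MB-II per w level quantify the score-vs-w
    relationship.
    """
    task = task or TaskConfig(n_trials=n_trials)
    rr = {**UNIFORM_RANGES, **(ranges or {})}
    tab, dk, du, umax, nk, nu = _table_args()
    blocks = block_ids(n_trials, task.n_blocks)
    lo, hi = task.walk_bounds
    rng = np.random.default_rng(seed)
    seeds = _child_seeds(seed + 7, len(w_grid) * n_experiments * 2).reshape(
        len(w_grid), n_experiments, 2)
    mask = np.ones(n_trials, dtype=np.bool_)
    tidx = np.arange(n_trials)

    rows = []
    dq_best_all, dq_worst_all = [], []
    for iw, w in enumerate(w_grid):
        mb1s, mb2s = [], []
        dqb, dqw, dqc, dqr, pbest = [], [], [], [], []
        for e in range(n_experiments):
            nui = {n: rng.uniform(*rr[n]) for n in _NUISANCE}
            walk = K.gen_walk(n_trials, task.walk_sd, lo, hi,
                              int(seeds[iw, e, 0]))
            c1, s2, tr, c2, rew, rt1, rt2, dq0, dq1, best = K.simulate_ddm(
                walk, blocks, task.p_common,
                nui["alpha1"], nui["alpha2"], nui["lam"], float(w), nui["p"],
                nui["b1"], nui["a1"], nui["tau1"],
                nui["b2"], nui["a2"], nui["tau2"],
                -1.0, tab, dk, du, umax, nk, nu, int(seeds[iw, e, 1]))
            ssum, sn, rsum, rn = K.score_cells(c1, tr, rew, rt2, tidx,
                                               blocks, mask, mask)
            mb1s.append((ssum[0] / sn[0] - ssum[2] / sn[2])
                        - (ssum[1] / sn[1] - ssum[3] / sn[3]))
            mb2s.append(rsum[1] / rn[1] - rsum[0] / rn[0])
            dq_by_state = np.stack([dq0, dq1])
            dq_best = dq_by_state[best, tidx]
            dq_worst = dq_by_state[1 - best, tidx]
            dqb.append(dq_best.mean())
            dqw.append(dq_worst.mean())
            visited_dq = dq_by_state[s2, tidx]
            common = tr == 0
            dqc.append(visited_dq[common].mean())
            dqr.append(visited_dq[~common].mean())
            pbest.append(np.mean((s2 == best) & common))
        rows.append({"w": float(w),
                     "mb1_mean": float(np.mean(mb1s)),
                     "mb2_mean": float(np.mean(mb2s)),
                     "dq_visited_common": float(np.mean(dqc)),
                     "dq_visited_rare": float(np.mean(dqr)),
                     "dq_best": float(np.mean(dqb)),
                     "dq_worst": float(np.mean(dqw)),
                     "p_best_via_common": float(np.mean(pbest))})
        dq_best_all.extend(dqb)
        dq_worst_all.extend(dqw)
    per_w = pd.DataFrame(rows)
    for c in ("mb1", "mb2"):
        m = per_w[f"{c}_mean"]
        per_w[f"{c}_z"] = (m - m.mean()) / m.std(ddof=1)
    return SweepResult(per_w, float(np.mean(dq_best_all)),
                       float(np.mean(dq_worst_all)),
                       n_experiments, n_trials)


# ---------------------------------------------------------------------------
# MANOVA and power
# ---------------------------------------------------------------------------


def manova_chi2(scores_a: np.ndarray, scores_b: np.ndarray):
    """Two-group MANOVA via Wilks' lambda with Bartlett's chi-square.

    Inputs are (n_i, p) score matrices.  Returns (chi2, df, p_value) with
    df = number of dependent variables (two-group case).  Raises on a
    singular total scatter matrix.
    """
    A = np.asarray(scores_a, dtype=float)
    B = np.asarray(scores_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("score matrices must be 2-D with equal column count")
    if len(A) < 3 or len(B) < 3:
        raise ValueError("need at least 3 subjects per group")
    p = A.shape[1]
    g = 2
    N = len(A) + len(B)
    X = np.vstack([A, B])
    T = (X - X.mean(axis=0)).T @ (X - X.mean(axis=0))
    W = sum((M - M.mean(axis=0)).T @ (M - M.mean(axis=0)) for M in (A, B))
    detT = np.linalg.det(T)
    detW = np.linalg.det(W)
    if not np.isfinite(detT) or abs(detT) < 1e-300:
        raise np.linalg.LinAlgError("singular scatter matrix")
    lam = detW / detT
    lam = min(max(lam, 1e-300), 1.0)
    chi2 = -(N - 1 - (p + g) / 2.0) * np.log(lam)
    df = p * (g - 1)
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


@dataclass
class PowerConfig:
    """Design of one simulated two-group comparison.

    ``effect_size`` maps to group w means: small .49/.51 (d = .2), medium
    .475/.525 (d = .5), large .46/.54 (d = .8), or 'null' (.5/.5) for
    type-I-error calibration; per-agent w is drawn from a Gaussian with
    SD ``w_sd`` truncated to [0, 1].
    """

    effect_size: str = "small"
    n_per_group: int = 30
    n_trials: int = 200
    n_iterations: int = 1000
    w_sd: float = 0.1
    alpha: float = 0.05
    seed: int = 0

    EFFECTS = {"small": (0.49, 0.51), "medium": (0.475, 0.525),
               "large": (0.46, 0.54), "null": (0.5, 0.5)}

    def group_means(self):
        if self.effect_size not in self.EFFECTS:
            raise ValueError(f"unknown effect size {self.effect_size!r}")
        return self.EFFECTS[self.effect_size]

    def __post_init__(self):
        if self.w_sd <= 0 or not (0 < self.alpha < 1):
            raise ValueError("w_sd and alpha must be positive (alpha < 1)")
        m1, m2 = self.group_means()
        if not (0 <= m1 <= 1 and 0 <= m2 <= 1):
            raise ValueError("group means must lie in [0, 1]")


@dataclass
class PowerResult:
    power: float
    n_significant: int
    n_ok: int
    n_failed: int
    ci_low: float
    ci_high: float
    config: PowerConfig


def _truncnorm01(rng, mean, sd, n):
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                               random_state=rng)


def power_analysis(config: PowerConfig,
                   task: Optional[TaskConfig] = None) -> PowerResult:
    """Monte-Carlo power of the two-group MANOVA on (MB-I, MB-II).

    Per iteration each group's w values are drawn from its truncated
    Gaussian, every agent's session is simulated under the diffusion model
    with nuisance parameters uniform in the canonical ranges, scores are
    computed and the MANOVA chi-square is tested at ``alpha``.  Agents
    with undefined scores are dropped within iteration; iterations that
    fail entirely (singular MANOVA) are excluded and counted.
    """
    task = task or TaskConfig(n_trials=config.n_trials)
    m_a, m_b = config.group_means()
    rng = np.random.default_rng(config.seed)
    seeds = _child_seeds(config.seed + 13, 2 * config.n_iterations)
    tab, dk, du, umax, nk, nu = _table_args()
    blocks = block_ids(config.n_trials, task.n_blocks)
    lo, hi = task.walk_bounds
    nui_lo = np.array([UNIFORM_RANGES[n][0] for n in _NUISANCE])
    nui_hi = np.array([UNIFORM_RANGES[n][1] for n in _NUISANCE])

    n_sig = n_ok = n_fail = 0
    for it in range(config.n_iterations):
        wa = _truncnorm01(rng, m_a, config.w_sd, config.n_per_group)
        wb = _truncnorm01(rng, m_b, config.w_sd, config.n_per_group)
        sa = K.ddm_cohort_scores(wa, config.n_trials, blocks, task.p_common,
                                 task.walk_sd, lo, hi, nui_lo, nui_hi,
                                 tab, dk, du, umax, nk, nu,
                                 int(seeds[2 * it]))
        sb = K.ddm_cohort_scores(wb, config.n_trials, blocks, task.p_common,
                                 task.walk_sd, lo, hi, nui_lo, nui_hi,
                                 tab, dk, du, umax, nk, nu,
                                 int(seeds[2 * it + 1]))
        sa = sa[np.isfinite(sa).all(axis=1)]
        sb = sb[np.isfinite(sb).all(axis=1)]
        try:
            _, _, pval = manova_chi2(sa, sb)
        except (np.linalg.LinAlgError, ValueError):
            n_fail += 1
            continue
        n_ok += 1
        if pval < config.alpha:
            n_sig += 1
    if n_ok == 0:
        raise RuntimeError("every power iteration failed")
    power = n_sig / n_ok
    lo_ci, hi_ci = stats.binomtest(n_sig, n_ok).proportion_ci(0.95)
    return PowerResult(power, n_sig, n_ok, n_fail,
                       float(lo_ci), float(hi_ci), config)
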