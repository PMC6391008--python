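"""Parameter estimation: individual ML, hierarchical EM, model comparison.

Individual fits maximise the model log-likelihood with a global
differential-evolution search over box bounds followed by a local polish;
this is deterministic given the seed and, with the default budget, reliably
finds the global optimum of these likelihoods (they are smooth in 7-11
dimensions).  Hierarchical fits treat each subject's parameters as
independent Gaussian random effects in an unconstrained (transformed)
space, alternating per-subject MAP estimation with a Laplace covariance
(E-step) and moment updates of the population mean and variance (M-step).
Model comparison uses the integrated BIC: minus twice the summed
Laplace-approximated subject log marginal likelihoods plus a complexity
penalty of (number of population hyperparameters) * log(total number of
observed responses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize

from . import _kernels as K
from .params import DDMRLParams, RLParams
from .task import SessionData, pack_session
from .ddm import DENSITY_ERR, DENSITY_FLOOR

__all__ = [
    "MODELS", "FitOptions", "FitResult", "GroupPrior", "HierarchicalResult",
    "fit_individual", "fit_hierarchical", "bic_int",
    "to_unconstrained", "to_constrained",
]


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

#: default box bounds by parameter kind
_DEFAULT_BOUNDS = {
    "unit": (0.0, 1.0),        # alpha, lam, w
    "beta": (0.01, 15.0),      # softmax inverse temperature
    "p": (-1.0, 1.0),          # perseveration
    "b": (0.05, 15.0),         # drift scaling
    "a": (0.2, 5.0),           # boundary separation
    "tau": (0.001, 1.0),       # non-decision time (s)
}

_KIND = {"alpha": "unit", "alpha1": "unit", "alpha2": "unit",
         "lam": "unit", "w": "unit",
         "beta": "beta", "beta1": "beta", "beta2": "beta",
         "p": "p", "b": "b", "b1": "b", "b2": "b",
         "a": "a", "a1": "a", "a2": "a",
         "tau": "tau", "tau1": "tau", "tau2": "tau"}

MODELS = {
    "rl5": ["alpha", "beta", "lam", "w", "p"],
    "rl7": ["alpha1", "alpha2", "beta1", "beta2", "lam", "w", "p"],
    "ddm8": ["alpha1", "alpha2", "lam", "w", "p", "b", "a", "tau"],
    "ddm11": ["alpha1", "alpha2", "lam", "w", "p",
              "b1", "a1", "tau1", "b2", "a2", "tau2"],
}


def default_bounds(model: str) -> list[tuple[float, float]]:
    return [_DEFAULT_BOUNDS[_KIND[n]] for n in MODELS[model]]


def params_from_vector(model: str, theta: np.ndarray):
    """Build the appropriate parameter dataclass from a fit vector."""
    t = [float(x) for x in theta]
    if model == "rl5":
        return RLParams.tied(*t)
    if model == "rl7":
        return RLParams(*t)
    if model == "ddm8":
        return DDMRLParams.tied(*t)
    if model == "ddm11":
        return DDMRLParams(*t)
    raise ValueError(f"unknown model {model!r}")


def _loglik_fn(model: str, session: SessionData):
    """Compiled log-likelihood as a function of the fit vector."""
    arr = pack_session(session)
    if arr["choice1"].size == 0:
        raise ValueError("empty session")
    a = (arr["choice1"], arr["state2"], arr["choice2"], arr["reward"])
    nb, pc = arr["new_block"], arr["p_common"]
    if model in ("rl5", "rl7"):
        if model == "rl5":
            def ll(th):
                al, be, lam, w, p = th
                return K.rl_loglik(al, al, be, be, lam, w, p, *a, nb, pc)
        else:
            def ll(th):
                return K.rl_loglik(*th, *a, nb, pc)
        return ll
    rts = (arr["rt1"], arr["rt2"])
    if np.any(~np.isfinite(arr["rt1"])) or np.any(~np.isfinite(arr["rt2"])):
        raise ValueError("DDM-RL fitting requires RTs on every trial")
    if model == "ddm8":
        def ll(th):
            a1, a2_, lam, w, p, b, bnd, tau = th
            return K.ddm_loglik(a1, a2_, lam, w, p, b, bnd, tau, b, bnd, tau,
                                *a, *rts, nb, pc, DENSITY_ERR, DENSITY_FLOOR)
    elif model == "ddm11":
        def ll(th):
            return K.ddm_loglik(*th, *a, *rts, nb, pc,
                                DENSITY_ERR, DENSITY_FLOOR)
    else:
        raise ValueError(f"unknown model {model!r}")
    return ll


# ---------------------------------------------------------------------------
# Options / results
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Optimizer settings.

    ``popsize`` and ``max_generations`` control the differential-evolution
    budget (total evaluations roughly popsize * dim * generations);
    ``n_restarts`` repeats the search with different seeds and keeps the
    best.  ``em_max_iter``/``em_tol`` govern the hierarchical EM loop.
    """

    method: str = "multistart_global"
    n_restarts: int = 1
    popsize: int = 15
    max_generations: int = 150
    seed: int = 0
    em_max_iter: int = 200
    em_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.popsize <= 0 or self.max_generations <= 0 or self.n_restarts <= 0:
            raise ValueError("optimizer budget must be positive")


@dataclass
class FitResult:
    model: str
    names: list[str]
    estimates: np.ndarray
    loglik: float
    converged: bool
    n_evaluations: int
    restarts: list[dict] = field(default_factory=list)

    @property
    def params(self):
        return params_from_vector(self.model, self.estimates)


@dataclass
class GroupPrior:
    """Per-parameter population Gaussian in unconstrained space."""

    names: list[str]
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")


@dataclass
class HierarchicalResult:
    model: str
    prior: GroupPrior
    subject_results: list[FitResult]
    log_evidence: np.ndarray  # per-subject Laplace log marginal likelihood
    converged: bool
    n_iter: int
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Transforms between constrained and unconstrained space
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _tkind(name: str) -> str:
    k = _KIND[name]
    if k == "unit":
        return "logit"
    if k == "p":
        return "identity"
    return "log"


def to_unconstrained(model: str, theta: np.ndarray) -> np.ndarray:
    z = np.array(theta, dtype=float)
    for i, n in enumerate(MODELS[model]):
        k = _tkind(n)
        if k == "logit":
            x = min(max(theta[i], _EPS), 1 - _EPS)
            z[i] = np.log(x / (1 - x))
        elif k == "log":
            z[i] = np.log(max(theta[i], _EPS))
    return z


def to_constrained(model: str, z: np.ndarray) -> np.ndarray:
    th = np.array(z, dtype=float)
    for i, n in enumerate(MODELS[model]):
        k = _tkind(n)
        if k == "logit":
            th[i] = 1.0 / (1.0 + np.exp(-z[i]))
        elif k == "log":
            th[i] = np.exp(z[i])
    return th


# ---------------------------------------------------------------------------
# Individual maximum likelihood
# ---------------------------------------------------------------------------


def fit_individual(model: str, session: SessionData,
                   opts: Optional[FitOptions] = None,
                   bounds: Optional[Sequence[tuple[float, float]]] = None,
                   ) -> FitResult:
    """Maximum-likelihood fit of one session by global optimisation.

    Deterministic given ``opts.seed``.  If every restart returns a
    non-finite objective the result is flagged ``converged=False`` (never
    silently raised).
    """
    opts = opts or FitOptions()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    bounds = list(bounds) if bounds is not None else default_bounds(model)
    ll = _loglik_fn(model, session)

    def neg(th):
        v = ll(th)
        return -v if np.isfinite(v) else 1e12

    restarts, n_eval = [], 0
    best = None
    for r in range(opts.n_restarts):
        res = differential_evolution(
            neg, bounds, seed=opts.seed + 1000003 * r,
            maxiter=opts.max_generations, popsize=opts.popsize,
            tol=1e-8, polish=True, init="sobol", updating="deferred")
        n_eval += int(res.nfev)
        restarts.append({"x": np.clip(res.x, [b[0] for b in bounds],
                                      [b[1] for b in bounds]),
                         "fun": float(res.fun), "nfev": int(res.nfev)})
        if best is None or res.fun < best["fun"]:
            best = restarts[-1]
    ok = np.isfinite(best["fun"]) and best["fun"] < 1e11
    if not ok:
        warnings.warn("all restarts returned non-finite likelihood; "
                      "fit flagged as failed")
    return FitResult(model=model, names=list(MODELS[model]),
                     estimates=np.asarray(best["x"], dtype=float),
                     loglik=-float(best["fun"]), converged=bool(ok),
                     n_evaluations=n_eval, restarts=restarts)


# ---------------------------------------------------------------------------
# Hierarchical EM with Laplace approximation
# ---------------------------------------------------------------------------

_VAR_FLOOR = 1e-6


def _num_hess(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian."""
    d = x.size
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h
        for j in range(i, d):
            ej = np.zeros(d); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4 * h**2)
    return H


def _subject_estep(ll, model, prior: GroupPrior, z0: np.ndarray):
    """MAP in unconstrained space + Laplace variance + log evidence."""
    finite = np.isfinite(prior.var)

    def nlp(z):
        v = ll(to_constrained(model, z))
        pen = 0.0
        if finite.any():
            d = z[finite] - prior.mean[finite]
            pen = 0.5 * np.sum(d * d / prior.var[finite]
                               + np.log(2 * np.pi * prior.var[finite]))
        return (-v if np.isfinite(v) else 1e12) + pen

    res = minimize(nlp, z0, method="L-BFGS-B")
    zmap = res.x
    H = _num_hess(nlp, zmap)
    d = zmap.size
    fallback = False
    try:
        cov = np.linalg.inv(H)
        lv = np.diag(cov).copy()
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0 or not np.all(np.isfinite(lv)) or np.any(lv <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        fallback = True
        lv = np.where(finite, prior.var, 1.0)
        logdet = float(np.sum(np.log(lv)))
    logz = -res.fun + 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet
    return zmap, lv, float(logz), fallback


def fit_hierarchical(model: str, sessions: Sequence[SessionData],
                     opts: Optional[FitOptions] = None,
                     bounds: Optional[Sequence[tuple[float, float]]] = None,
                     prior: Optional[GroupPrior] = None,
                     ) -> HierarchicalResult:
    """Expectation-maximisation fit of a cohort with Gaussian random effects.

    Initialised from budget-reduced individual fits unless a ``prior`` is
    supplied.  When a supplied prior has infinite variances and
    ``em_max_iter`` is 0-1, the E-step reduces to unregularised MAP = MLE.
    """
    opts = opts or FitOptions()
    if len(sessions) < 2 and prior is None:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    names = list(MODELS[model])
    lls = [_loglik_fn(model, s) for s in sessions]

    if prior is None:
        small = FitOptions(seed=opts.seed, popsize=max(6, opts.popsize // 2),
                           max_generations=max(30, opts.max_generations // 3))
        inits = [fit_individual(model, s, small, bounds) for s in sessions]
        zs = np.array([to_unconstrained(model, f.estimates) for f in inits])
        prior = GroupPrior(names, zs.mean(axis=0),
                           np.maximum(zs.var(axis=0), _VAR_FLOOR) + 0.25)
        zmaps = zs.copy()
    else:
        zmaps = np.tile(np.where(np.isfinite(prior.mean), prior.mean, 0.0),
                        (len(sessions), 1))

    warns: list[str] = []
    prev_ev = -np.inf
    converged = False
    it = 0
    logz = np.zeros(len(sessions))
    lvars = np.zeros_like(zmaps)
    for it in range(1, max(opts.em_max_iter, 1) + 1):
        for i, ll in enumerate(lls):
            zmaps[i], lvars[i], logz[i], fb = _subject_estep(
                ll, model, prior, zmaps[i])
            if fb:
                warns.append(f"subject {i}: singular Laplace Hessian, "
                             "prior-variance fallback")
        total = float(logz.sum())
        if np.isfinite(prev_ev) and abs(total - prev_ev) < opts.em_tol * (
                abs(prev_ev) + 1.0):
            converged = True
        prev_ev = total
        # M-step (skipped for frozen infinite-variance priors)
        if np.all(np.isfinite(prior.var)):
            mu = zmaps.mean(axis=0)
            var = (zmaps**2 + lvars).mean(axis=0) - mu**2
            prior = GroupPrior(names, mu, np.maximum(var, _VAR_FLOOR))
        if converged:
            break
    for w in set(warns):
        warnings.warn(w)

    subj = []
    for i in range(len(sessions)):
        th = to_constrained(model, zmaps[i])
        subj.append(FitResult(model=model, names=names, estimates=th,
                              loglik=float(lls[i](th)), converged=True,
                              n_evaluations=0))
    return HierarchicalResult(model=model, prior=prior, subject_results=subj,
                              log_evidence=logz.copy(), converged=converged,
                              n_iter=it, warnings=warns)


def bic_int(result: HierarchicalResult,
            sessions: Sequence[SessionData]) -> float:
    """Integrated BIC of a hierarchical fit (lower is better).

    ``-2 * sum_subjects logZ_subject + n_hyper * log(N_obs)`` where the
    hyperparameters are the population mean and variance of every model
    parameter and an observation is one recorded response (two stages per
    trial).
    """
    if not result.converged:
        warnings.warn("hierarchical fit did not converge; BIC_int may be "
                      "unreliable")
    n_obs = 2 * sum(s.n_trials for s in sessions)
    n_hyper = 2 * len(result.prior.names)
    return float(-2.0 * result.log_evidence.sum() + n_hyper * np.log(n_obs))
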