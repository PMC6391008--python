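"""Wiener diffusion first-passage machinery and the DDM-RL likelihood.

The decision process at each task stage is a one-dimensional Wiener
diffusion with unit noise SD, drift :math:`\\delta`, absorbing boundaries
separated by :math:`a`, and the accumulator starting midway between them
(no prior response bias).  The upper boundary represents the option that
was eventually chosen, so the trial drift is
:math:`\\delta = b\\,(Q_\\text{chosen} - Q_\\text{unchosen})` with a free
scaling parameter :math:`b`; observed RT is first-passage time plus a
non-decision time :math:`\\tau`.

The first-passage density is evaluated with the classical pair of
absolutely convergent series (a small-time expansion in Gaussian images
and a large-time eigenfunction expansion), switching per evaluation to
whichever needs fewer terms for the requested tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K

__all__ = [
    "WienerSpec",
    "wiener_fpt_density",
    "wiener_fpt_cdf",
    "absorption_prob",
    "sample_fpt",
    "euler_fpt_sample",
    "ddmrl_loglik",
    "DENSITY_ERR",
    "DENSITY_FLOOR",
]

#: absolute truncation tolerance of the density series (normalised units)
DENSITY_ERR = 1e-8
#: density floor used inside likelihoods so that rt <= tau or far-tail RTs
#: contribute log(DENSITY_FLOOR) instead of -inf
DENSITY_FLOOR = 1e-10


@dataclass(frozen=True)
class WienerSpec:
    """Parameters of a single diffusion decision.

    ``rel_start`` and ``noise_sd`` are fixed by the model (unbiased start,
    unit scaling) but kept as explicit fields so degenerate variants can be
    probed in tests.
    """

    boundary_sep: float
    drift: float
    rel_start: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.boundary_sep > 0):
            raise ValueError("boundary separation must be positive")
        if not (0.0 < self.rel_start < 1.0):
            raise ValueError("relative start must lie strictly inside (0, 1)")
        if self.noise_sd != 1.0:
            raise ValueError("the noise SD is fixed to 1 for identifiability")


def wiener_fpt_density(t, spec: WienerSpec, boundary: str = "upper",
                       err: float = DENSITY_ERR):
    """First-passage density at time(s) ``t`` through the given boundary.

    Vectorised over ``t``.  Raises for non-positive ``t``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    tarr = np.asarray(t, dtype=float)
    if np.any(tarr <= 0):
        raise ValueError("first-passage time must be positive")
    v, w = spec.drift, spec.rel_start
    if boundary == "upper":
        v, w = -v, 1.0 - w
    flat = np.atleast_1d(tarr).ravel()
    out = np.empty_like(flat)
    for i in range(flat.size):
        out[i] = K.wfpt_lower(flat[i], v, spec.boundary_sep, w, err)
    out = out.reshape(np.atleast_1d(tarr).shape)
    return float(out[0]) if tarr.ndim == 0 else out


def absorption_prob(spec: WienerSpec, boundary: str = "upper") -> float:
    """Probability of ever exiting through the given boundary."""
    v, a, w = spec.drift, spec.boundary_sep, spec.rel_start
    if v == 0.0:
        p_upper = w
    else:
        # P(upper) = (1 - exp(-2 v z)) / (1 - exp(-2 v a)), z = w a
        p_upper = np.expm1(-2.0 * v * w * a) / np.expm1(-2.0 * v * a)
    return float(p_upper if boundary == "upper" else 1.0 - p_upper)


def wiener_fpt_cdf(t, spec: WienerSpec, boundary: str = "upper",
                   n_terms: int = 400):
    """Cumulative first-passage probability through one boundary by time t.

    Computed from the term-by-term integral of the large-time expansion;
    converges for all t > 0 (slowly for very small normalised t, hence the
    generous default term count).  ``wiener_fpt_cdf(inf) = absorption_prob``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    v, a, w = spec.drift, spec.boundary_sep, spec.rel_start
    if boundary == "upper":
        v, w = -v, 1.0 - w
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    k = np.arange(1, n_terms + 1)[:, None]
    lam = v * v + (k * np.pi / a) ** 2  # decay rate of each mode (x2)
    coef = 2.0 * k * np.pi * np.sin(k * np.pi * w) / (a * a * lam)
    tail = np.empty_like(tarr)
    with np.errstate(over="ignore", under="ignore"):
        for lo in range(0, tarr.size, 65536):  # chunked: bounded memory
            sl = slice(lo, lo + 65536)
            tail[sl] = np.exp(-v * a * w) * (
                coef * np.exp(-lam * tarr[None, sl] / 2.0)).sum(axis=0)
    p_exit = absorption_prob(
        WienerSpec(a, -v if boundary == "upper" else v, w if boundary == "lower" else 1 - w),
        boundary)
    out = np.clip(p_exit - tail, 0.0, 1.0)
    out[tarr <= 0.0] = 0.0
    return float(out[0]) if np.asarray(t).ndim == 0 else out


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

#: kappa = a*|drift| grid resolution of the conditional quantile table
_KAPPA_MAX = 40.0
_NK = 321
_NU = 1024
_UMAX = 1.0 - 2.0 ** -12
_TGRID = np.geomspace(1e-4, 12.0, 4096)

_table_cache: dict[str, np.ndarray] = {}


def _quantile_table() -> np.ndarray:
    """Conditional FPT quantile table q[kappa_i, u_j] in normalised units.

    Built lazily once per process: the conditional (boundary-independent,
    start = a/2) density is tabulated per kappa, integrated with the
    trapezoid rule, normalised and inverted onto a uniform probability grid.
    """
    tab = _table_cache.get("qtab")
    if tab is not None:
        return tab
    kappas = np.linspace(0.0, _KAPPA_MAX, _NK)
    dens = K.fill_conditional_density(kappas, _TGRID, DENSITY_ERR)
    mid = 0.5 * (dens[:, 1:] + dens[:, :-1]) * np.diff(_TGRID)[None, :]
    cdf = np.concatenate([np.zeros((_NK, 1)), np.cumsum(mid, axis=1)], axis=1)
    cdf /= cdf[:, -1:]
    ugrid = np.linspace(0.0, _UMAX, _NU)
    tab = np.empty((_NK, _NU))
    for i in range(_NK):
        tab[i] = np.interp(ugrid, cdf[i], _TGRID)
    _table_cache["qtab"] = tab
    return tab


def _table_args():
    tab = _quantile_table()
    dk = _KAPPA_MAX / (_NK - 1)
    du = _UMAX / (_NU - 1)
    return tab, dk, du, _UMAX, _NK, _NU


def sample_fpt(spec: WienerSpec, rng: np.random.Generator,
               size: int | None = None):
    """Draw (boundary, decision_time) pairs from the first-passage law.

    Exploits the fact that with an unbiased start the exit side and the
    exit time are independent: the side is Bernoulli with the analytic
    absorption probability and the time is drawn by inverting the
    tabulated conditional CDF.  Returns (boundary, t) scalars when ``size``
    is None, else two arrays; boundary is 1 for upper, 0 for lower.
    """
    tab, dk, du, umax, nk, nu = _table_args()
    n = 1 if size is None else int(size)
    a, v = spec.boundary_sep, spec.drift
    kappa = a * v
    p_up = 1.0 / (1.0 + np.exp(-kappa))
    seed = int(rng.integers(0, 2**31 - 1))
    b, t = _sample_fpt_batch(a, kappa, p_up, n, tab, dk, du, umax, nk, nu, seed)
    if size is None:
        return int(b[0]), float(t[0])
    return b, t


def euler_fpt_sample(spec: WienerSpec, n: int, dt: float = 1e-4,
                     seed: int = 0):
    """Brute-force Euler-Maruyama first-passage sampler (reference oracle).

    Uses Brownian-bridge crossing probabilities between grid points and a
    midpoint time correction; independent of the series density code path.
    """
    return K.euler_fpt(spec.boundary_sep, spec.drift, spec.rel_start,
                       dt, n, seed)


from numba import njit  # noqa: E402  (local import keeps top clean)


@njit(cache=True)
def _sample_fpt_batch(a, kappa, p_up, n, qtab, dk, du, umax, nk, nu, seed):
    np.random.seed(seed)
    b = np.empty(n, np.int8)
    t = np.empty(n)
    for i in range(n):
        b[i] = 1 if np.random.random() < p_up else 0
        t[i] = a * a * K.sample_fpt_norm(abs(kappa), qtab, dk, du, umax, nk, nu)
    return b, t


# ---------------------------------------------------------------------------
# DDM-RL likelihood
# ---------------------------------------------------------------------------


def ddmrl_loglik(params, session, err: float = DENSITY_ERR,
                 floor: float = DENSITY_FLOOR) -> float:
    """Joint choice + RT log-likelihood of a session under the DDM-RL model.

    Stage-1 drifts use the net (MB/MF-mixed, perseveration-bonused) values,
    stage-2 drifts the model-free values within the visited state, with the
    value recursion rolled forward trial by trial.
    """
    from .task import pack_session  # late import to avoid cycle

    arr = pack_session(session)
    if arr["choice1"].size == 0:
        raise ValueError("empty session")
    th = params.as_array()
    if not np.all(np.isfinite(th)):
        raise ValueError("non-finite parameters")
    if np.any(~np.isfinite(arr["rt1"])) or np.any(~np.isfinite(arr["rt2"])):
        raise ValueError("DDM-RL likelihood requires RTs on every trial")
    return float(K.ddm_loglik(
        *th,
        arr["choice1"], arr["state2"], arr["choice2"], arr["reward"],
        arr["rt1"], arr["rt2"], arr["new_block"], arr["p_common"],
        err, floor))
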