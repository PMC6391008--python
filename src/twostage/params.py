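"""Parameter vectors for the hybrid RL and DDM-RL models.

Both models share the five learning parameters of the hybrid
model-based/model-free learner: stage learning rates ``alpha1``/``alpha2``
(in [0, 1]), eligibility trace ``lam`` (in [0, 1]) weighting how strongly the
second-stage prediction error reaches the first-stage value, the mixture
weight ``w`` (0 = pure model-free, 1 = pure model-based) and a perseveration
bonus ``p`` for repeating the previous first-stage choice.

The choice-only model adds stage softmax inverse temperatures
``beta1``/``beta2``; the joint choice + RT model instead adds per-stage
diffusion parameters: drift scaling ``b``, boundary separation ``a`` and
non-decision time ``tau`` (seconds).

The reduced variants of each model tie the stage-specific parameters
(5-parameter RL: alpha1 = alpha2, beta1 = beta2; 8-parameter DDM-RL:
b1 = b2, a1 = a2, tau1 = tau2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RLParams", "DDMRLParams"]


def _check_unit(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


@dataclass(frozen=True)
class RLParams:
    """Hybrid learner with softmax choice rule (7 free parameters)."""

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    lam: float
    w: float
    p: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "lam", "w"):
            _check_unit(name, getattr(self, name))
        for name in ("beta1", "beta2"):
            if not (getattr(self, name) >= 0.0):
                raise ValueError(f"{name} must be non-negative")
        if not np.isfinite(self.p):
            raise ValueError("perseveration must be finite")

    @classmethod
    def tied(cls, alpha: float, beta: float, lam: float, w: float,
             p: float) -> "RLParams":
        """5-parameter variant with stage-shared alpha and beta."""
        return cls(alpha, alpha, beta, beta, lam, w, p)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.beta1, self.beta2,
                         self.lam, self.w, self.p], dtype=float)


@dataclass(frozen=True)
class DDMRLParams:
    """Hybrid learner with diffusion choice + RT rule (11 free parameters)."""

    alpha1: float
    alpha2: float
    lam: float
    w: float
    p: float
    b1: float
    a1: float
    tau1: float
    b2: float
    a2: float
    tau2: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "lam", "w"):
            _check_unit(name, getattr(self, name))
        if not np.isfinite(self.p):
            raise ValueError("perseveration must be finite")
        for name in ("a1", "a2"):
            if not (getattr(self, name) > 0.0):
                raise ValueError(f"{name} must be positive")
        for name in ("tau1", "tau2"):
            if not (getattr(self, name) >= 0.0):
                raise ValueError(f"{name} must be non-negative")
        for name in ("b1", "b2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def tied(cls, alpha1: float, alpha2: float, lam: float, w: float,
             p: float, b: float, a: float, tau: float) -> "DDMRLParams":
        """8-parameter variant with stage-shared diffusion parameters."""
        return cls(alpha1, alpha2, lam, w, p, b, a, tau, b, a, tau)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.lam, self.w, self.p,
                         self.b1, self.a1, self.tau1,
                         self.b2, self.a2, self.tau2], dtype=float)
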