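"""Noise specification and symmetric α-stable sampling.

The stochastic model perturbs the basal synthesis rate with two independent
additive noises: a standard Brownian motion with intensity ``sigma`` and a
standard symmetric α-stable Lévy motion (pure jump, characteristic function
exp(-t|ξ|^α)) with intensity ``epsilon``.  The stability index
``alpha ∈ (0, 2]`` sets the jump-size/frequency trade-off: small α means
rare, very large jumps; α = 2 degenerates to Gaussian.

The relative contribution factor (RCF) λ = ε/σ measures the non-Gaussian
share; under the constraint ε + σ = 1 it parametrises the mix with one
number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

__all__ = ["NoiseSpec", "sample_standard_stable", "levy_jump_constant"]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian intensity σ, Lévy intensity ε and stability index α.

    ``constrained=True`` enforces the ε + σ = 1 normalisation used in the
    RCF sweeps.  ``lambda_rcf`` is the derived ratio ε/σ (+inf when σ = 0).
    """

    sigma: float
    epsilon: float
    alpha: float = 2.0
    constrained: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.epsilon < 0:
            raise ValueError("noise intensities must be nonnegative")
        if not 0 < self.alpha <= 2:
            raise ValueError(f"alpha must lie in (0, 2], got {self.alpha}")
        if self.constrained:
            if abs(self.sigma + self.epsilon - 1.0) > 1e-12:
                raise ValueError("sigma + epsilon must equal 1 in constrained mode")
            if not 0 < self.sigma <= 1:
                raise ValueError("sigma must lie in (0, 1] in constrained mode")

    @property
    def lambda_rcf(self) -> float:
        if self.sigma == 0.0:
            return math.inf
        return self.epsilon / self.sigma


def levy_jump_constant(alpha: float) -> float:
    """Normalising constant C_α of the jump measure ν_α(dy) = C_α |y|^{-1-α} dy.

    C_α = α Γ((1+α)/2) / (2^{1-α} √π Γ(1-α/2)); with this constant the
    principal-value jump integral is the generator of the standard symmetric
    α-stable motion (C_1 = 1/π, the Cauchy case).
    """
    if not 0 < alpha < 2:
        raise ValueError("jump measure defined for 0 < alpha < 2")
    return (
        alpha
        * _gamma((1 + alpha) / 2)
        / (2 ** (1 - alpha) * math.sqrt(math.pi) * _gamma(1 - alpha / 2))
    )


def sample_standard_stable(
    alpha: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. standard symmetric α-stable variates (CMS transform).

    Chambers–Mallows–Stuck: with U uniform on (-π/2, π/2) and W
    exponential(1),

        X = sin(αU)/cos(U)^{1/α} * (cos((1-α)U)/W)^{(1-α)/α}

    α = 1 reduces to X = tan(U) (standard Cauchy); α = 2 is N(0, 2).
    The draw order is U first, then W.
    """
    if not 0 < alpha <= 2:
        raise ValueError(f"alpha must lie in (0, 2], got {alpha}")
    if alpha == 2.0:
        return rng.normal(0.0, math.sqrt(2.0), size=n)
    u = rng.uniform(-math.pi / 2, math.pi / 2, size=n)
    if alpha == 1.0:
        return np.tan(u)
    w = rng.exponential(1.0, size=n)
    au = alpha * u
    return (
        np.sin(au)
        / np.cos(u) ** (1.0 / alpha)
        * (np.cos(u - au) / w) ** ((1.0 - alpha) / alpha)
    )
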