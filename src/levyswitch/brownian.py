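r"""Closed-form exit quantities for the pure-diffusion (Brownian) case.

For dX = f(X) dt + sigma dB on a single interval (a, b) with absorption at
both ends, define the scale density

    psi(x) = exp( -(2/sigma^2) * \int_a^x f(s) ds )

Then the probability of exiting right before left is the scale-function
ratio p(x) = \int_a^x psi / \int_a^b psi, and the mean exit time has the
classical double-quadrature form

    u(x) = (2/sigma^2) * [ p(x) G(b) - G(x) ],
    G(x) = \int_a^x psi(t) \int_a^t psi(y)^{-1} dy dt.

These serve as independent oracles for the finite-difference solver; the
nested integrals are accumulated by adaptive high-order integration
(tolerance ~1e-11).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .domains import Domain1D
from .model import as_drift

__all__ = ["brownian_mfet_closed_form", "brownian_fep_closed_form"]


def _single_interval(domain) -> tuple[float, float]:
    if isinstance(domain, Domain1D):
        if len(domain.intervals) != 1:
            raise ValueError("closed forms exist for single-interval domains only")
        return domain.intervals[0]
    a, b = domain
    return float(a), float(b)


def _scale_integrals(model, sigma: float, a: float, b: float):
    """Dense-output antiderivatives (Phi, s, H, G) on [a, b]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    f = as_drift(model)
    c = 2.0 / (sigma * sigma)

    def rhs(x, y):
        phi_exp = np.exp(-c * y[0])
        return [float(f(x)), phi_exp, 1.0 / phi_exp, phi_exp * y[2]]

    sol = solve_ivp(
        rhs,
        (a, b),
        [0.0, 0.0, 0.0, 0.0],
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"quadrature failed: {sol.message}")
    return sol.sol, c


def brownian_mfet_closed_form(model, sigma: float, domain, x):
    """Mean exit time of the diffusion from (a, b), evaluated at x."""
    a, b = _single_interval(domain)
    dense, c = _scale_integrals(model, sigma, a, b)
    _, s_b, _, G_b = dense(b)
    x = np.asarray(x, dtype=float)
    vals = dense(np.atleast_1d(x))
    s_x, G_x = vals[1], vals[3]
    u = c * (s_x / s_b * G_b - G_x)
    return float(u[0]) if x.ndim == 0 else u


def brownian_fep_closed_form(model, sigma: float, domain, x):
    """Probability that the diffusion exits (a, b) through b rather than a."""
    a, b = _single_interval(domain)
    dense, _ = _scale_integrals(model, sigma, a, b)
    s_b = dense(b)[1]
    x = np.asarray(x, dtype=float)
    p = dense(np.atleast_1d(x))[1] / s_b
    return float(p[0]) if x.ndim == 0 else p
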