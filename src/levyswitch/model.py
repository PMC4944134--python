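"""Deterministic TF-A autoregulation model.

A transcription factor activator (TF-A) in a positive feedback loop:
phosphorylated TF-A homodimers bind responsive elements of their own gene
and activate transcription at maximal rate ``k_f``; the monomer is degraded
at rate ``k_d`` and synthesised at a basal rate ``R_bas``.  With dimer
binding taken to be fast, the monomer concentration ``x`` obeys

    dx/dt = k_f * x**2 / (x**2 + K_d) - k_d * x + R_bas

For suitable rates the system is bistable: a low concentration state
``x_minus``, an unstable threshold ``x_u`` and a high concentration state
``x_plus``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ModelParams",
    "Equilibria",
    "drift",
    "potential",
    "find_equilibria",
    "classify_stability",
    "as_drift",
]


@dataclass(frozen=True)
class ModelParams:
    """Kinetic rates of the TF-A model.

    Parameters
    ----------
    k_f : float
        Maximal transcription rate (1/min).
    K_d : float
        Dissociation constant of the dimer from the responsive element
        (enters the Hill term un-squared).
    k_d : float
        First-order degradation rate of the monomer (1/min).
    R_bas : float
        Basal synthesis rate (nM/min).
    """

    k_f: float
    K_d: float
    k_d: float
    R_bas: float

    def __post_init__(self) -> None:
        for name in ("k_f", "K_d", "k_d", "R_bas"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class Equilibria:
    """Fixed points of the drift, sorted ascending.

    ``bistable`` is true when there are three roots; then
    ``0 < x_minus < x_u < x_plus`` with the outer two stable and the
    middle one unstable.  For a monostable system only ``x_minus`` is set.
    """

    roots: tuple[float, ...]
    bistable: bool

    @property
    def x_minus(self) -> float:
        return self.roots[0]

    @property
    def x_u(self) -> float:
        if not self.bistable:
            raise ValueError("monostable system has no unstable state")
        return self.roots[1]

    @property
    def x_plus(self) -> float:
        if not self.bistable:
            raise ValueError("monostable system has no high state")
        return self.roots[2]


def drift(x, params: ModelParams):
    """Right-hand side f(x) of the TF-A rate equation (nM/min).

    Accepts scalars or arrays.  Negative ``x`` is permitted — jump paths can
    overshoot below zero and the formula is evaluated as written.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("drift: non-finite concentration")
    out = params.k_f * x * x / (x * x + params.K_d) - params.k_d * x + params.R_bas
    return out if out.ndim else float(out)


def as_drift(model) -> Callable[[np.ndarray], np.ndarray]:
    """Return a vectorised drift callable from ``ModelParams`` or a callable.

    Several solver and oracle routines are parameter-generic; this lets
    textbook drifts (e.g. ``f = 0``) stand in for the TF-A model in tests.
    """
    if isinstance(model, ModelParams):
        return lambda x: drift(x, model)
    if callable(model):
        return model
    raise TypeError(f"expected ModelParams or callable, got {type(model)!r}")


def potential(x, params: ModelParams):
    """Potential energy V with V' = -drift and the normalisation V(0) = 0.

    Computed by adaptive quadrature of ``-drift`` from 0, which keeps the
    routine generic in the parameters (a closed form exists but is not
    needed anywhere at this accuracy).
    """
    f = as_drift(params)

    def _one(xi: float) -> float:
        if not np.isfinite(xi):
            raise ValueError("potential: non-finite concentration")
        val, _ = quad(lambda s: -f(s), 0.0, xi, epsabs=1e-12, epsrel=1e-10, limit=200)
        return val

    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        return _one(float(x))
    return np.array([_one(xi) for xi in x.ravel()]).reshape(x.shape)


def _bisect(f: Callable[[float], float], a: float, b: float) -> float:
    """Bisection to bracket width 1e-12; returns the midpoint."""
    fa = f(a)
    while b - a > 1e-12:
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            return m
        if fa * fm < 0:
            b = m
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def find_equilibria(
    params: ModelParams, search_max: float = 10.0, n_scan: int = 8192
) -> Equilibria:
    """Locate all roots of the drift on [0, search_max].

    Sign changes are bracketed on a uniform scan grid and refined by
    bisection.  Bistability is decided by root counting: one root means
    monostable, three means bistable.  Two roots indicate a tangency
    (saddle-node) within tolerance and raise; the model admits at most
    three fixed points, so more than three also raise.
    """
    if search_max <= 0:
        raise ValueError("search_max must be positive")
    f = lambda x: float(drift(x, params))
    xs = np.linspace(0.0, search_max, n_scan + 1)
    ys = np.array([f(x) for x in xs])
    roots: list[float] = []
    for i in range(n_scan):
        if ys[i] == 0.0:
            roots.append(float(xs[i]))
        elif ys[i] * ys[i + 1] < 0:
            roots.append(_bisect(f, float(xs[i]), float(xs[i + 1])))
    if ys[-1] == 0.0:
        roots.append(float(xs[-1]))
    roots = sorted(roots)
    if len(roots) == 0:
        raise ValueError("no equilibrium found on [0, search_max]")
    if len(roots) == 2:
        raise ValueError("tangency (saddle-node) detected: two roots")
    if len(roots) > 3:
        raise ValueError(f"model admits at most three fixed points, found {len(roots)}")
    for r in roots:
        if abs(f(r)) > 1e-8:
            raise RuntimeError(f"root refinement failed at x={r}: |f|={abs(f(r)):.2e}")
    return Equilibria(roots=tuple(roots), bistable=len(roots) == 3)


def _fprime(model, x: float, h: float = 1e-6) -> float:
    f = as_drift(model)
    return float((f(x + h) - f(x - h)) / (2 * h))


def classify_stability(params: ModelParams, x: float) -> str:
    """Classify an equilibrium as ``"stable"`` or ``"unstable"`` by sign of f'."""
    f = as_drift(params)
    if abs(float(f(x))) > 1e-6:
        raise ValueError(f"x={x} is not an equilibrium (|f|={abs(float(f(x))):.2e})")
    return "stable" if _fprime(params, x) < 0 else "unstable"
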