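"""Escape analysis: RCF sweeps and the stochastic basin of attraction.

The relative contribution factor (RCF) λ = ε/σ fixes the Gaussian /
Lévy mix under the normalisation ε + σ = 1, so a sweep over λ traces the
response of the mean first exit time and the escape probability to the
noise composition at constant total intensity.

The stochastic basin of attraction (SBA) of the low-concentration state
replaces the deterministic basin with a noise-aware construct: a closed
core K where the mean residence time exceeds a threshold u*, united with
the set M of outside points whose probability of entering K exceeds p*.
Its size (interval length) quantifies basin stability under noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .domains import Domain1D
from .model import ModelParams, find_equilibria
from .noise import NoiseSpec
from .solver import FieldSolution, solve_fep, solve_mfet

__all__ = [
    "RCFSetting",
    "intensities_from_rcf",
    "noise_from_rcf",
    "sweep_mfet",
    "sweep_fep",
    "extract_K",
    "ustar_for_width",
    "stochastic_basin",
    "SBAResult",
]

SWEEP_COLUMNS = [
    "x0",
    "alpha",
    "sigma",
    "epsilon",
    "lambda",
    "scenario",
    "quantity",
    "value",
]


def intensities_from_rcf(lambda_rcf: float) -> tuple[float, float]:
    """(sigma, epsilon) with epsilon/sigma = lambda and sigma + epsilon = 1."""
    if not np.isfinite(lambda_rcf) or lambda_rcf < 0:
        raise ValueError("lambda_rcf must be finite and nonnegative")
    return 1.0 / (1.0 + lambda_rcf), lambda_rcf / (1.0 + lambda_rcf)


@dataclass(frozen=True)
class RCFSetting:
    """A point of the constrained noise family, parametrised by λ."""

    lambda_rcf: float

    @property
    def sigma(self) -> float:
        return intensities_from_rcf(self.lambda_rcf)[0]

    @property
    def epsilon(self) -> float:
        return intensities_from_rcf(self.lambda_rcf)[1]

    def noise(self, alpha: float) -> NoiseSpec:
        return NoiseSpec(self.sigma, self.epsilon, alpha, constrained=True)


def noise_from_rcf(lambda_rcf: float, alpha: float) -> NoiseSpec:
    return RCFSetting(lambda_rcf).noise(alpha)


def _as_noise(setting, alpha: float) -> NoiseSpec:
    if isinstance(setting, NoiseSpec):
        return setting
    if isinstance(setting, RCFSetting):
        return setting.noise(alpha)
    sigma, epsilon = setting
    return NoiseSpec(float(sigma), float(epsilon), alpha)


def _rows(x0_list, noise, quantity, scenario, sol) -> list[dict]:
    lam = noise.lambda_rcf
    return [
        {
            "x0": float(x0),
            "alpha": noise.alpha,
            "sigma": noise.sigma,
            "epsilon": noise.epsilon,
            "lambda": lam if math.isfinite(lam) else np.inf,
            "scenario": scenario,
            "quantity": quantity,
            "value": float(sol(x0)),
        }
        for x0 in x0_list
    ]


def sweep_mfet(
    x0_list: Sequence[float],
    alpha: float,
    settings: Iterable,
    domain: Domain1D,
    model,
    J: int = 400,
) -> pd.DataFrame:
    """One MFET solve per noise setting, interpolated at each start point."""
    rows: list[dict] = []
    for setting in settings:
        noise = _as_noise(setting, alpha)
        sol = solve_mfet(domain, model, noise, J)
        rows += _rows(x0_list, noise, "mfet", 0, sol)
    return (
        pd.DataFrame(rows, columns=SWEEP_COLUMNS)
        .sort_values(["x0", "lambda"], kind="stable")
        .reset_index(drop=True)
    )


def sweep_fep(
    x0_list: Sequence[float],
    alpha: float,
    settings: Iterable,
    domain: Domain1D,
    target: Domain1D,
    scenario: int,
    model,
    J: int = 400,
) -> pd.DataFrame:
    """One FEP solve per noise setting; ``scenario`` is recorded per row.

    Scenario 1: target adjacent to the domain (e.g. [x_u, inf)).
    Scenario 2: target separated from the domain — reachable only by jumps.
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    if scenario == 2:
        for a, b in target.intervals:
            for c, d in domain.intervals:
                if a == d or b == c:
                    raise ValueError("scenario 2 requires a non-adjacent target")
    rows: list[dict] = []
    for setting in settings:
        noise = _as_noise(setting, alpha)
        sol = solve_fep(domain, target, model, noise, J)
        rows += _rows(x0_list, noise, "fep", scenario, sol)
    return (
        pd.DataFrame(rows, columns=SWEEP_COLUMNS)
        .sort_values(["x0", "lambda"], kind="stable")
        .reset_index(drop=True)
    )


def _superlevel_component(
    xs: np.ndarray, vs: np.ndarray, level: float, i_peak: int
) -> tuple[float, float]:
    """Connected component of {v >= level} containing index ``i_peak``,
    endpoints located by linear interpolation across the level."""
    lo = xs[i_peak]
    i = i_peak
    while i > 0 and vs[i - 1] >= level:
        i -= 1
    if i > 0:
        t = (vs[i] - level) / (vs[i] - vs[i - 1])
        lo = xs[i] - t * (xs[i] - xs[i - 1])
    else:
        lo = xs[0]
    i = i_peak
    while i < vs.size - 1 and vs[i + 1] >= level:
        i += 1
    if i < vs.size - 1:
        t = (vs[i] - level) / (vs[i] - vs[i + 1])
        hi = xs[i] + t * (xs[i + 1] - xs[i])
    else:
        hi = xs[-1]
    return float(lo), float(hi)


def extract_K(u: FieldSolution, u_star: float) -> tuple[float, float]:
    """Closed superlevel interval {u >= u*} around the MFET maximum.

    If the superlevel set is disconnected (possible at coarse grids) the
    component containing the (leftmost) maximiser is taken.
    """
    if u_star <= 0:
        raise ValueError("u_star must be positive")
    best = None
    for m in range(u.grid.n_intervals):
        xs, vs = u.interval_arrays(m)
        i = int(np.argmax(vs))
        if best is None or vs[i] > best[2][best[1]]:
            best = (xs, i, vs)
    xs, i_peak, vs = best
    if u_star > vs[i_peak]:
        raise ValueError(f"empty K: u_star={u_star} exceeds max(u)={vs[i_peak]:.6g}")
    return _superlevel_component(xs, vs, u_star, i_peak)


def ustar_for_width(u: FieldSolution, width: float, tol: float = 1e-10) -> float:
    """Threshold u* whose superlevel interval {u >= u*} has a given width.

    Useful for comparing basins across noise laws at matched |K|.
    """
    u_max = max(float(np.max(u.interval_arrays(m)[1])) for m in range(u.grid.n_intervals))
    lo, hi = 0.0, u_max  # width decreases in u*
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid <= 0:
            break
        a, b = extract_K(u, mid)
        if b - a > width:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * u_max:
            break
    return 0.5 * (lo + hi)


def _superlevel_intervals(
    p: FieldSolution,
    p_star: float,
    core_side: Optional[list[tuple[bool, bool]]] = None,
) -> list[tuple[float, float]]:
    """Union of intervals {p > p*}, endpoints interpolated, per solve interval.

    ``core_side[m] = (left, right)`` marks interval ends that touch the
    core set K; such an endpoint belongs to K, not to its complement, so
    its prescribed value 1 must not seed a component by itself — it
    inherits the status of the adjacent interior node instead.
    """
    out: list[tuple[float, float]] = []
    for m in range(p.grid.n_intervals):
        xs, vs = p.interval_arrays(m)
        vs = np.clip(vs, 0.0, 1.0)
        above = vs > p_star
        if core_side is not None:
            left, right = core_side[m]
            if left:
                above[0] = above[1]
            if right:
                above[-1] = above[-2]
        k = 0
        while k < vs.size:
            if above[k]:
                j = k
                while j + 1 < vs.size and above[j + 1]:
                    j += 1
                lo = xs[k]
                if k > 0:
                    t = (vs[k] - p_star) / (vs[k] - vs[k - 1])
                    lo = xs[k] - t * (xs[k] - xs[k - 1])
                hi = xs[j]
                if j < vs.size - 1:
                    t = (vs[j] - p_star) / (vs[j] - vs[j + 1])
                    hi = xs[j] + t * (xs[j + 1] - xs[j])
                if hi > lo:
                    out.append((float(lo), float(hi)))
                k = j + 1
            else:
                k += 1
    return out


@dataclass
class SBAResult:
    """Stochastic basin of attraction of the core set K.

    ``sba_size = |K| + |M|`` is the basin volume (interval length).
    """

    K: tuple[float, float]
    M: list[tuple[float, float]]
    u_star: float
    p_star: float
    window: Domain1D
    sba_size: float
    u: FieldSolution = field(repr=False, default=None)
    p: FieldSolution = field(repr=False, default=None)

    @property
    def K_length(self) -> float:
        return self.K[1] - self.K[0]

    @property
    def M_length(self) -> float:
        return sum(b - a for a, b in self.M)


def stochastic_basin(
    model,
    noise: NoiseSpec,
    window: Domain1D,
    u_star: float,
    p_star: float,
    J: int = 400,
    basin: Optional[Domain1D] = None,
) -> SBAResult:
    """Quantify the stochastic basin of the low-concentration state.

    Steps: (i) solve the MFET on the deterministic basin interval (default
    (0, x_u) from the model's equilibria); (ii) K = {u >= u*} around the
    maximum; (iii) solve the return probability to K on the two-interval
    region window \\ K with the indicator of K as exterior condition
    (everything outside the window returns 0); (iv) M = {p > p*};
    (v) size = |K| + |M|.
    """
    if not window.bounded or len(window.intervals) != 1:
        raise ValueError("window must be a single bounded interval")
    if not 0 < p_star < 1:
        raise ValueError("p_star must lie in (0, 1)")
    if basin is None:
        if not isinstance(model, ModelParams):
            raise ValueError("provide `basin` explicitly for a bare drift callable")
        eq = find_equilibria(model)
        basin = Domain1D.interval(0.0, eq.x_u)
    u = solve_mfet(basin, model, noise, J)
    k_lo, k_hi = extract_K(u, u_star)
    w_lo, w_hi = window.intervals[0]
    if k_lo <= w_lo or k_hi >= w_hi:
        warnings.warn("K touches the search window boundary", stacklevel=2)
    ret_domain = Domain1D([(w_lo, k_lo), (k_hi, w_hi)])
    p = solve_fep(ret_domain, Domain1D.interval(k_lo, k_hi), model, noise, J)
    M = _superlevel_intervals(p, p_star, core_side=[(False, True), (True, False)])
    size = (k_hi - k_lo) + sum(b - a for a, b in M)
    return SBAResult(
        K=(k_lo, k_hi),
        M=M,
        u_star=u_star,
        p_star=p_star,
        window=window,
        sba_size=size,
        u=u,
        p=p,
    )
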