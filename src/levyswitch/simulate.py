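"""Euler–Maruyama simulation of the jump diffusion and Monte Carlo exit
estimators.

The scheme for dX = f(X) dt + sigma dB + epsilon dL^alpha is

    X_{n+1} = X_n + f(X_n) dt + sigma sqrt(dt) G_n + epsilon dt^{1/alpha} S_n

with G_n standard Gaussian and S_n standard symmetric alpha-stable; the
dt^{1/alpha} scaling is the self-similarity of the stable motion.  Both
noise streams are drawn from one seeded generator in a fixed order
(Gaussian first, then stable), so runs are exactly reproducible from
(seed, dt, n_paths); a stream whose intensity is zero is not drawn.

Exit bookkeeping keeps the post-jump overshoot: the exit state is the
first position outside the open domain, with no boundary interpolation
(the O(sqrt(dt)) Gaussian crossing bias is accepted at the default step).
Negative concentrations are allowed in the raw process; the drift is
evaluated as written.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .domains import Domain1D
from .model import as_drift
from .noise import NoiseSpec, sample_standard_stable

__all__ = [
    "Trajectory",
    "ExitEnsemble",
    "MCEstimate",
    "simulate_path",
    "mc_first_exit",
    "mc_mfet",
    "mc_fep",
]

DEFAULT_SEED = 20160714


@dataclass
class Trajectory:
    """A single sample path on a uniform time grid."""

    times: np.ndarray
    states: np.ndarray
    dt: float
    seed: Optional[int] = None
    truncated: bool = False


@dataclass
class ExitEnsemble:
    """First-exit records of a path ensemble started at ``x0`` in ``domain``.

    ``exit_times[i]`` is the time of the first step outside the open
    domain; censored paths (no exit before the step cap) keep the horizon
    time and are flagged in ``censored``.
    """

    exit_times: np.ndarray
    exit_states: np.ndarray
    censored: np.ndarray
    x0: float
    domain: Domain1D
    dt: float

    @property
    def n(self) -> int:
        return self.exit_times.size

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


@dataclass(frozen=True)
class MCEstimate:
    """A Monte Carlo mean or proportion with its standard error."""

    value: float
    std_error: float
    n: int

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise ValueError("standard error must be nonnegative")


def simulate_path(
    model,
    noise: NoiseSpec,
    x0: float,
    dt: float,
    t_max: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Trajectory:
    """Simulate one path on [0, t_max] with step dt.

    A non-finite state (overflow after a huge jump) truncates the path and
    sets the ``truncated`` flag.
    """
    if dt <= 0 or t_max < dt:
        raise ValueError("need dt > 0 and t_max >= dt")
    if rng is None:
        rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    f = as_drift(model)
    n = int(round(t_max / dt))
    sig_dt = noise.sigma * math.sqrt(dt)
    eps_dt = noise.epsilon * dt ** (1.0 / noise.alpha)
    xs = np.empty(n + 1)
    xs[0] = x0
    x = float(x0)
    truncated = False
    for k in range(n):
        step = float(f(x)) * dt
        if sig_dt > 0:
            step += sig_dt * rng.standard_normal()
        if eps_dt > 0:
            step += eps_dt * float(sample_standard_stable(noise.alpha, 1, rng)[0])
        x += step
        if not math.isfinite(x) or abs(x) > 1e12:
            truncated = True
            xs = xs[: k + 1]
            n = k
            break
        xs[k + 1] = x
    times = np.arange(xs.size) * dt
    return Trajectory(times=times, states=xs, dt=dt, seed=seed, truncated=truncated)


def mc_first_exit(
    model,
    noise: NoiseSpec,
    domain: Domain1D,
    x0: float,
    n_paths: int = 10_000,
    dt: float = 1e-3,
    t_max: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    max_steps: int = 1_000_000,
) -> ExitEnsemble:
    """Vectorised first-exit sampling for ``n_paths`` paths from ``x0``.

    With ``t_max=None`` the simulation runs until every path has exited or
    the hard cap ``max_steps`` is hit; otherwise it stops at t_max.  A
    censoring fraction above 5% triggers a warning (the MFET estimate is
    then biased low).
    """
    if rng is None:
        rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    f = as_drift(model)
    exit_times = np.zeros(n_paths)
    exit_states = np.full(n_paths, float(x0))
    censored = np.zeros(n_paths, dtype=bool)

    if not domain.contains(x0, strict=True):
        return ExitEnsemble(exit_times, exit_states, censored, x0, domain, dt)

    n_cap = max_steps if t_max is None else min(max_steps, int(round(t_max / dt)))
    sig_dt = noise.sigma * math.sqrt(dt)
    eps_dt = noise.epsilon * dt ** (1.0 / noise.alpha)
    if sig_dt == 0 and eps_dt == 0:
        raise ValueError("at least one noise intensity must be positive")

    x = np.full(n_paths, float(x0))
    alive = np.arange(n_paths)
    step_no = 0
    while alive.size and step_no < n_cap:
        step_no += 1
        dx = f(x[alive]) * dt
        if sig_dt > 0:
            dx = dx + sig_dt * rng.standard_normal(alive.size)
        if eps_dt > 0:
            dx = dx + eps_dt * sample_standard_stable(noise.alpha, alive.size, rng)
        x[alive] += dx
        out = ~domain.contains(x[alive], strict=True)
        if out.any():
            gone = alive[out]
            exit_times[gone] = step_no * dt
            exit_states[gone] = x[gone]
            alive = alive[~out]
    if alive.size:
        censored[alive] = True
        exit_times[alive] = step_no * dt
        exit_states[alive] = x[alive]
        frac = alive.size / n_paths
        if frac > 0.05:
            warnings.warn(
                f"{100 * frac:.1f}% of paths censored at the step cap; "
                "MFET will be biased low",
                stacklevel=2,
            )
    return ExitEnsemble(exit_times, exit_states, censored, x0, domain, dt)


def mc_mfet(ens: ExitEnsemble) -> MCEstimate:
    """Sample mean of the exit times with its standard error."""
    if ens.n == 0:
        raise ValueError("empty ensemble")
    if ens.n_censored > 0:
        warnings.warn(
            f"{ens.n_censored} censored paths included; mean exit time biased low",
            stacklevel=2,
        )
    t = ens.exit_times
    se = 0.0 if ens.n == 1 else float(t.std(ddof=1) / math.sqrt(ens.n))
    return MCEstimate(value=float(t.mean()), std_error=se, n=ens.n)


def mc_fep(ens: ExitEnsemble, target: Domain1D) -> MCEstimate:
    """Proportion of paths whose exit state lands in ``target``."""
    if not target.disjoint_from(ens.domain):
        raise ValueError("target must lie in the complement of the exit domain")
    hit = target.contains(ens.exit_states, strict=False) & ~ens.censored
    p = float(hit.mean())
    se = math.sqrt(p * (1.0 - p) / ens.n)
    return MCEstimate(value=p, std_error=se, n=ens.n)
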