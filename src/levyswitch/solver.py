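r"""Finite-difference solver for nonlocal exit problems.

The generator of the jump diffusion

    dX = f(X) dt + sigma dB_t + epsilon dL_t^alpha

acting on a test function u is

    A u(x) = f(x) u'(x) + (sigma^2/2) u''(x)
             + eps^alpha * PV \int (u(x+y) - u(x)) C_alpha |y|^{-1-alpha} dy

(the small-jump compensator vanishes by symmetry).  The mean first exit
time u from an open set D solves A u = -1 in D with u = 0 on the whole
complement; the first escape probability p to a target set E solves
A p = 0 in D with p = 1 on E and p = 0 on the rest of the complement
(Balayage–Dirichlet exterior condition).

Discretisation on a uniform grid per interval of D:

* drift: central difference, switching to first-order upwind at nodes
  where the cell Péclet number |f| h / (2 nu) exceeds 1 (nu = local
  diffusion coefficient), which keeps the system matrix an M-matrix in
  the jump-dominated regime;
* Gaussian part: second central difference;
* jump integral: punched-hole composite trapezoid over the grid beyond
  the singular cell |y| < h, the singular cell replaced by its effective
  diffusion C_alpha h^{2-alpha}/(2-alpha) u''(x), and every exterior
  interval integrated against the jump measure analytically (closed-form
  tail masses — no numerical truncation of the jump integral).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import solve as dense_solve
from scipy.linalg import solve_banded

from .domains import Domain1D, ExteriorCondition
from .model import as_drift
from .noise import NoiseSpec, levy_jump_constant

__all__ = [
    "Grid",
    "GeneratorMatrix",
    "FieldSolution",
    "assemble_generator",
    "solve_mfet",
    "solve_fep",
    "refine_until",
]


@dataclass(frozen=True)
class Grid:
    """Uniform lattice over each interval of a bounded domain.

    Each interval (a, b) is mapped affinely onto z in (-1, 1) and carries
    ``J`` cells, i.e. J - 1 interior nodes at x_k = a + k h, h = (b-a)/J.
    Interval endpoints are lattice points but belong to the exterior.
    """

    domain: Domain1D
    J: int

    def __post_init__(self) -> None:
        if not self.domain.bounded:
            raise ValueError("solve domain must be bounded")
        if self.J < 17:
            raise ValueError("need at least 16 interior nodes per interval (J >= 17)")

    @property
    def h(self) -> tuple[float, ...]:
        return tuple((b - a) / self.J for a, b in self.domain.intervals)

    def lattice(self, m: int) -> np.ndarray:
        """All lattice points of interval m, endpoints included."""
        a, b = self.domain.intervals[m]
        return a + np.arange(self.J + 1) * ((b - a) / self.J)

    @property
    def nodes(self) -> np.ndarray:
        """Interior nodes of every interval, concatenated."""
        return np.concatenate([self.lattice(m)[1:-1] for m in range(self.n_intervals)])

    @property
    def n_intervals(self) -> int:
        return len(self.domain.intervals)

    @property
    def n_nodes(self) -> int:
        return self.n_intervals * (self.J - 1)

    def to_z(self, m: int, x):
        a, b = self.domain.intervals[m]
        return (2.0 * (np.asarray(x) - a) / (b - a)) - 1.0


@dataclass
class GeneratorMatrix:
    """Discretised generator restricted to the interior nodes.

    ``matrix @ v + load`` approximates (A v) at the interior nodes when v
    carries the interior nodal values and the exterior takes its
    prescribed values (folded into ``load``).  ``tail_mass`` holds, per
    node, the total analytic jump-measure mass of the exterior
    (the part of the integral never truncated numerically).
    """

    grid: Grid
    matrix: np.ndarray
    load: np.ndarray
    tail_mass: np.ndarray
    is_tridiagonal: bool

    def apply(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ v + self.load


def _halve(w: np.ndarray, idx) -> None:
    for k in set(idx):
        w[k] *= 0.5


def assemble_generator(
    grid: Grid,
    model,
    noise: NoiseSpec,
    exterior: ExteriorCondition,
) -> GeneratorMatrix:
    """Assemble the generator matrix and exterior load on ``grid``.

    ``model`` is a ``ModelParams`` or any vectorised drift callable.
    ``alpha = 2`` (or ``epsilon = 0``) routes the jump part to pure
    diffusion: a standard 2-stable increment has variance 2 dt, so it adds
    ``epsilon**2`` to the diffusion coefficient.
    """
    f = as_drift(model)
    domain = grid.domain
    exterior.check_against(domain)

    sig, eps, alpha = noise.sigma, noise.epsilon, noise.alpha
    use_jump = eps > 0 and alpha < 2
    diff0 = 0.5 * sig * sig + (eps * eps if (eps > 0 and alpha == 2) else 0.0)
    if not use_jump and diff0 == 0.0:
        raise ValueError("no noise: the exit-time problem is degenerate")
    if use_jump:
        C = levy_jump_constant(alpha)
        s = eps**alpha

    J = grid.J
    nI = grid.n_intervals
    N = grid.n_nodes
    lattices = [grid.lattice(m) for m in range(nI)]
    hs = grid.h
    offsets = [m * (J - 1) for m in range(nI)]
    bval = [
        (
            exterior.boundary_value(domain, domain.intervals[m][0], "left"),
            exterior.boundary_value(domain, domain.intervals[m][1], "right"),
        )
        for m in range(nI)
    ]
    pieces = exterior.pieces(domain)

    M = np.zeros((N, N))
    load = np.zeros(N)
    tail = np.zeros(N)

    for m in range(nI):
        h = hs[m]
        P = lattices[m]
        bl, br = bval[m]
        corr = s * C * h ** (2.0 - alpha) / (2.0 - alpha) if use_jump else 0.0
        diff = diff0 + corr
        fvals = np.asarray(f(P[1:-1]), dtype=float)

        for i in range(1, J):
            g = offsets[m] + i - 1
            x = P[i]
            fj = float(fvals[i - 1])

            # --- local part: drift + diffusion (+ singular-cell correction)
            cL = cR = diff / (h * h)
            cD = -2.0 * diff / (h * h)
            if diff > 0 and abs(fj) * h / (2.0 * diff) <= 1.0:
                cL -= fj / (2.0 * h)
                cR += fj / (2.0 * h)
            elif fj > 0:  # upwind, characteristics to the right
                cR += fj / h
                cD -= fj / h
            elif fj < 0:
                cL += -fj / h
                cD -= -fj / h
            M[g, g] += cD
            if i - 1 >= 1:
                M[g, g - 1] += cL
            else:
                load[g] += cL * bl
            if i + 1 <= J - 1:
                M[g, g + 1] += cR
            else:
                load[g] += cR * br

            if not use_jump:
                continue

            # --- nonlocal part, same interval: punched-hole trapezoid over
            # [a, x_{i-1}] and [x_{i+1}, b] (half weights at segment ends)
            w = np.full(J + 1, h)
            _halve(w, (0, i - 1, i + 1, J))
            w[i] = 0.0
            if i == 1:
                w[0] = 0.0  # left segment [a, x-h] is empty
            if i == J - 1:
                w[J] = 0.0
            d = np.abs(P - x)
            d[i] = 1.0  # excluded anyway
            ker = s * C * w / d ** (1.0 + alpha)
            M[g, g] -= ker.sum()
            load[g] += ker[0] * bl + ker[J] * br
            idx = np.nonzero(ker[1:J])[0]  # local interior lattice indices -1
            M[g, offsets[m] + idx] += ker[1:J][idx]

            # --- nonlocal part, other intervals of a multi-interval domain
            for n in range(nI):
                if n == m:
                    continue
                Pn, hn = lattices[n], hs[n]
                wn = np.full(J + 1, hn)
                _halve(wn, (0, J))
                dn = np.abs(Pn - x)
                if dn.min() < 0.5 * h:
                    raise ValueError("domain intervals closer than half a grid cell")
                kern = s * C * wn / dn ** (1.0 + alpha)
                M[g, g] -= kern.sum()
                bln, brn = bval[n]
                load[g] += kern[0] * bln + kern[J] * brn
                M[g, offsets[n] : offsets[n] + J - 1] += kern[1:J]

            # --- exterior: analytic jump-measure integrals piece by piece
            for pa, pb, val in pieces:
                if pb <= x:
                    near, far = x - pb, x - pa
                else:
                    near, far = pa - x, pb - x
                mass = (C / alpha) * (
                    near ** (-alpha) - (far ** (-alpha) if np.isfinite(far) else 0.0)
                )
                tail[g] += mass
                M[g, g] -= s * mass
                load[g] += s * val * mass

    return GeneratorMatrix(
        grid=grid,
        matrix=M,
        load=load,
        tail_mass=tail,
        is_tridiagonal=not use_jump,
    )


@dataclass
class FieldSolution:
    """Nodal values of u(x) (MFET, minutes) or p(x) (FEP, probability).

    Evaluation at arbitrary x in the closed domain is piecewise linear,
    using the prescribed exterior values at the interval endpoints; FEP
    values are clipped to [0, 1] on evaluation (raw nodal values are kept
    in ``values`` for diagnostics).
    """

    grid: Grid
    values: np.ndarray
    kind: str
    boundary_values: tuple[tuple[float, float], ...]
    convergence: list = field(default_factory=list)

    def interval_arrays(self, m: int) -> tuple[np.ndarray, np.ndarray]:
        """(x, value) arrays of interval m including its endpoints."""
        J = self.grid.J
        xs = self.grid.lattice(m)
        lo, hi = m * (J - 1), (m + 1) * (J - 1)
        bl, br = self.boundary_values[m]
        vs = np.concatenate([[bl], self.values[lo:hi], [br]])
        return xs, vs

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.full(x.shape, np.nan)
        for m in range(self.grid.n_intervals):
            a, b = self.grid.domain.intervals[m]
            sel = (x >= a) & (x <= b)
            if sel.any():
                xs, vs = self.interval_arrays(m)
                out[sel] = np.interp(x[sel], xs, vs)
        if np.isnan(out).any():
            raise ValueError("evaluation point outside the solve domain")
        if self.kind == "fep":
            out = np.clip(out, 0.0, 1.0)
        return float(out[0]) if scalar else out


def _solve_linear(gm: GeneratorMatrix, rhs: np.ndarray) -> np.ndarray:
    if gm.is_tridiagonal:
        N = gm.matrix.shape[0]
        ab = np.zeros((3, N))
        ab[0, 1:] = np.diag(gm.matrix, 1)
        ab[1] = np.diag(gm.matrix)
        ab[2, :-1] = np.diag(gm.matrix, -1)
        return solve_banded((1, 1), ab, rhs)
    return dense_solve(gm.matrix, rhs)


def _boundary_values(
    domain: Domain1D, exterior: ExteriorCondition
) -> tuple[tuple[float, float], ...]:
    return tuple(
        (
            exterior.boundary_value(domain, a, "left"),
            exterior.boundary_value(domain, b, "right"),
        )
        for a, b in domain.intervals
    )


def solve_mfet(
    domain: Domain1D, model, noise: NoiseSpec, J: int = 400
) -> FieldSolution:
    """Mean first exit time from ``domain``: A u = -1, u = 0 outside."""
    grid = Grid(domain, J)
    ext = ExteriorCondition("zero")
    gm = assemble_generator(grid, model, noise, ext)
    u = _solve_linear(gm, -np.ones(gm.matrix.shape[0]) - gm.load)
    if u.min() < -1e-8:
        raise RuntimeError(f"MFET solve produced negative times (min {u.min():.2e})")
    return FieldSolution(grid, u, "mfet", _boundary_values(domain, ext))


def solve_fep(
    domain: Domain1D, target: Domain1D, model, noise: NoiseSpec, J: int = 400
) -> FieldSolution:
    """First escape probability from ``domain`` into ``target``:
    A p = 0 in D, p = indicator of the target on the complement."""
    grid = Grid(domain, J)
    ext = ExteriorCondition("indicator", target=target)
    gm = assemble_generator(grid, model, noise, ext)
    p = _solve_linear(gm, -gm.load)
    if p.min() < -1e-6 or p.max() > 1 + 1e-6:
        raise RuntimeError(
            f"FEP solve left [0,1] beyond tolerance: [{p.min():.3e}, {p.max():.3e}]"
        )
    return FieldSolution(grid, p, "fep", _boundary_values(domain, ext))


def refine_until(
    domain: Domain1D,
    model,
    noise: NoiseSpec,
    *,
    kind: str = "mfet",
    target: Optional[Domain1D] = None,
    tol: float = 1e-3,
    J0: int = 100,
    J_max: int = 6400,
) -> FieldSolution:
    """Double the resolution until the solution stops moving.

    Successive solutions are compared at the coarser grid's nodes; the
    relative sup-norm change must fall below ``tol``.  The convergence
    history [(J, change), ...] is attached to the returned solution.
    ``tol = inf`` returns the first solve unchanged.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    solver = (
        (lambda J: solve_mfet(domain, model, noise, J))
        if kind == "mfet"
        else (lambda J: solve_fep(domain, target, model, noise, J))
    )
    sol = solver(J0)
    history: list[tuple[int, float]] = [(J0, np.inf)]
    if not np.isfinite(tol):
        sol.convergence = history
        return sol
    J = J0
    while J <= J_max // 2:
        J *= 2
        new = solver(J)
        xs = sol.grid.nodes
        scale = max(np.max(np.abs(new(xs))), 1e-300)
        change = float(np.max(np.abs(new(xs) - sol(xs))) / scale)
        history.append((J, change))
        sol = new
        if change < tol:
            sol.convergence = history
            return sol
    raise RuntimeError(
        f"no convergence to tol={tol} by J={J_max}; history={history}"
    )
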