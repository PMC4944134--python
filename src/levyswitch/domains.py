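"""One-dimensional domains and exterior (Balayage–Dirichlet) conditions.

Nonlocal exit problems prescribe the solution on the entire complement of
the solve region, not just at its boundary: a jump can land anywhere
outside.  ``Domain1D`` is a finite union of disjoint open intervals;
``ExteriorCondition`` assigns a value to every point of the complement —
zero (mean-first-exit-time problems), the indicator of a target set
(escape-probability problems) or a constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = ["Domain1D", "ExteriorCondition"]

_INF = float("inf")


@dataclass(frozen=True)
class Domain1D:
    """Ordered union of disjoint open intervals (a_i, b_i).

    Endpoints may be infinite for target/exterior sets; domains used as
    solve regions must be bounded (checked by the solver).
    """

    intervals: tuple[tuple[float, float], ...]

    def __init__(self, intervals: Iterable[tuple[float, float]]):
        ivs = tuple((float(a), float(b)) for a, b in intervals)
        if not ivs:
            raise ValueError("domain must contain at least one interval")
        for a, b in ivs:
            if not a < b:
                raise ValueError(f"degenerate interval ({a}, {b})")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if not b0 <= a1:
                raise ValueError("intervals must be disjoint and ordered")
        object.__setattr__(self, "intervals", ivs)

    @classmethod
    def interval(cls, a: float, b: float) -> "Domain1D":
        return cls([(a, b)])

    @property
    def bounded(self) -> bool:
        return np.isfinite(self.intervals[0][0]) and np.isfinite(self.intervals[-1][1])

    @property
    def length(self) -> float:
        return sum(b - a for a, b in self.intervals)

    def contains(self, x, strict: bool = True):
        """Membership test; ``strict=True`` treats intervals as open
        (solve regions), ``strict=False`` as closed (targets)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape, dtype=bool)
        for a, b in self.intervals:
            if strict:
                out |= (x > a) & (x < b)
            else:
                out |= (x >= a) & (x <= b)
        return out if out.ndim else bool(out)

    def complement(self) -> list[tuple[float, float]]:
        """Closed complement as a list of (possibly infinite) intervals."""
        pieces: list[tuple[float, float]] = []
        lo = -_INF
        for a, b in self.intervals:
            if lo < a:
                pieces.append((lo, a))
            lo = b
        if lo < _INF:
            pieces.append((lo, _INF))
        return pieces

    def disjoint_from(self, other: "Domain1D") -> bool:
        for a, b in self.intervals:
            for c, d in other.intervals:
                if max(a, c) < min(b, d):
                    return False
        return True


@dataclass(frozen=True)
class ExteriorCondition:
    """Value prescribed on the whole complement of the solve domain.

    kind ``"zero"``: 0 everywhere outside (MFET).
    kind ``"indicator"``: 1 on ``target``, 0 elsewhere outside (FEP).
    kind ``"constant"``: ``value`` everywhere outside.
    """

    kind: str
    target: Optional[Domain1D] = None
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "indicator", "constant"):
            raise ValueError(f"unknown exterior condition kind {self.kind!r}")
        if self.kind == "indicator" and self.target is None:
            raise ValueError("indicator condition requires a target set")

    def check_against(self, domain: Domain1D) -> None:
        if self.kind == "indicator" and not self.target.disjoint_from(domain):
            raise ValueError("target set overlaps the solve domain")

    def pieces(self, domain: Domain1D) -> list[tuple[float, float, float]]:
        """Split the complement of ``domain`` into constant-value pieces
        (a, b, value).  Used for analytic jump-measure integration."""
        self.check_against(domain)
        comp = domain.complement()
        if self.kind == "zero":
            return [(a, b, 0.0) for a, b in comp]
        if self.kind == "constant":
            return [(a, b, self.value) for a, b in comp]
        out: list[tuple[float, float, float]] = []
        for a, b in comp:
            cuts = sorted(
                {a, b}
                | {e for iv in self.target.intervals for e in iv if a < e < b}
            )
            for lo, hi in zip(cuts, cuts[1:]):
                mid = 0.5 * (lo + hi)
                if not np.isfinite(mid):  # semi-infinite piece
                    mid = hi - 1.0 if np.isfinite(hi) else lo + 1.0
                val = 1.0 if self.target.contains(mid, strict=False) else 0.0
                out.append((lo, hi, val))
        return out

    def boundary_value(self, domain: Domain1D, endpoint: float, side: str) -> float:
        """Exterior value in the limit just outside ``endpoint``.

        ``side`` is ``"left"`` for a left endpoint of a solve interval
        (exterior lies below) and ``"right"`` for a right endpoint.
        """
        eps = 1e-12 * max(1.0, abs(endpoint))
        probe = endpoint - eps if side == "left" else endpoint + eps
        for a, b, v in self.pieces(domain):
            if a <= probe <= b:
                return v
        raise RuntimeError("endpoint probe fell outside every exterior piece")
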