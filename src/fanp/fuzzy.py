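"""Triangular fuzzy numbers (TFNs) and their arithmetic.

A TFN ``(l, m, u)`` encodes an uncertain positive ratio judgment: ``l`` is
the smallest plausible value, ``m`` the most plausible (modal) value and
``u`` the largest plausible value, with a piecewise-linear membership
function rising from ``l`` to ``m`` and falling from ``m`` to ``u``.  The
degenerate case ``l == m == u`` is an ordinary crisp number.

Everything downstream (pairwise comparison matrices, fuzzy weight vectors)
is built from the handful of operations defined here: componentwise
multiplication, the fuzzy reciprocal, the geometric mean, and
defuzzification (Liou–Wang total integral or centroid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TFN",
    "tfn_invert",
    "tfn_multiply",
    "tfn_add",
    "tfn_geomean",
    "defuzzify",
    "DEFUZZIFY_METHODS",
]

#: Absolute tolerance for floating comparisons of O(1) judgment ratios.
DEFAULT_TOL = 1e-9

DEFUZZIFY_METHODS = ("total_integral", "centroid")


@dataclass(frozen=True)
class TFN:
    """A triangular fuzzy number ``(l, m, u)`` with ``0 < l <= m <= u``."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (self.l > 0):
            raise ValueError(f"TFN components must be positive, got l={self.l}")
        if not (self.l <= self.m <= self.u):
            raise ValueError(
                f"TFN requires l <= m <= u, got ({self.l}, {self.m}, {self.u})"
            )

    @classmethod
    def crisp(cls, value: float) -> "TFN":
        """Degenerate TFN representing an exact value."""
        return cls(value, value, value)

    @property
    def is_crisp(self) -> bool:
        return self.l == self.m == self.u

    def __iter__(self) -> Iterator[float]:
        yield self.l
        yield self.m
        yield self.u

    def __mul__(self, other: "TFN") -> "TFN":
        return tfn_multiply(self, other)

    def __add__(self, other: "TFN") -> "TFN":
        return tfn_add(self, other)

    def inverse(self) -> "TFN":
        return tfn_invert(self)

    def approx_equal(self, other: "TFN", tol: float = DEFAULT_TOL) -> bool:
        return (
            abs(self.l - other.l) <= tol
            and abs(self.m - other.m) <= tol
            and abs(self.u - other.u) <= tol
        )

    def to_list(self) -> list[float]:
        """Serialize as the ordered triple ``[l, m, u]``."""
        return [self.l, self.m, self.u]


def tfn_invert(a: TFN) -> TFN:
    """Fuzzy reciprocal: ``(l, m, u) -> (1/u, 1/m, 1/l)``.

    The bounds swap so the result is again ordered.  This is the entry used
    to fill the lower triangle of a reciprocal comparison matrix.
    """
    return TFN(1.0 / a.u, 1.0 / a.m, 1.0 / a.l)


def tfn_multiply(a: TFN, b: TFN) -> TFN:
    """Componentwise product, the standard TFN multiplication approximation."""
    return TFN(a.l * b.l, a.m * b.m, a.u * b.u)


def tfn_add(a: TFN, b: TFN) -> TFN:
    """Componentwise sum (exact for TFNs)."""
    return TFN(a.l + b.l, a.m + b.m, a.u + b.u)


def tfn_geomean(items: Sequence[TFN] | Iterable[TFN]) -> TFN:
    """Componentwise geometric mean of one or more TFNs.

    Used both for Buckley's row geometric mean and for aggregating a panel
    of experts cell by cell; the geometric mean is the aggregation rule that
    preserves reciprocity.
    """
    items = list(items)
    if not items:
        raise ValueError("tfn_geomean requires a non-empty sequence of TFNs")
    n = len(items)
    # sum of logs is better conditioned than a product of n O(1) factors
    sl = sm = su = 0.0
    for t in items:
        sl += math.log(t.l)
        sm += math.log(t.m)
        su += math.log(t.u)
    return TFN(math.exp(sl / n), math.exp(sm / n), math.exp(su / n))


def defuzzify(a: TFN, method: str = "total_integral", alpha: float = 0.5) -> float:
    """Map a TFN to a crisp value.

    ``total_integral`` is the Liou–Wang total integral value with optimism
    index ``alpha``: ``alpha*(m+u)/2 + (1-alpha)*(l+m)/2``.  At
    ``alpha = 0.5`` this reduces to the familiar ``(l + 2m + u)/4``.
    ``centroid`` returns ``(l + m + u)/3``.  Either way the result lies in
    ``[l, u]``.
    """
    if method == "total_integral":
        if not (0.0 <= alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
        return alpha * (a.m + a.u) / 2.0 + (1.0 - alpha) * (a.l + a.m) / 2.0
    if method == "centroid":
        return (a.l + a.m + a.u) / 3.0
    raise ValueError(f"unknown defuzzification method {method!r}; expected one of {DEFUZZIFY_METHODS}")
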