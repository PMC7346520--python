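"""Elicitation scale, reciprocal pairwise comparison matrices, expert panels.

Judgments are elicited on Saaty's 9-point scale (1 = equal importance,
9 = extreme importance of one element over another).  Each integer score is
fuzzified to a TFN with a configurable spread ``delta``; reciprocal scores
map to the fuzzy reciprocal.  A comparison question yields a square
reciprocal matrix of TFNs; a panel of experts yields one such matrix per
expert per question, aggregated cell by cell with the geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .fuzzy import TFN, tfn_geomean, tfn_invert

__all__ = [
    "FuzzyScale",
    "FuzzyComparisonMatrix",
    "ExpertPanel",
    "ReciprocityReport",
    "scale_to_tfn",
    "validate_reciprocal",
    "aggregate_panel",
]


@dataclass(frozen=True)
class FuzzyScale:
    """Fuzzification of the 9-point judgment scale.

    Score ``s`` maps to ``(max(s - delta, 1), s, min(s + delta, 9))`` with
    score 1 pinned to the crisp ``(1, 1, 1)``; reciprocal scores ``1/s`` map
    to the fuzzy reciprocal, so the scale is reciprocal-consistent by
    construction.
    """

    delta: float = 1.0
    ceiling: float = 9.0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("scale spread delta must be non-negative")

    def tfn(self, score: float) -> TFN:
        """TFN for an integer score in 1..9; use :func:`scale_to_tfn` for reciprocals."""
        if not (1 <= score <= self.ceiling):
            raise ValueError(f"score {score} outside 1..{self.ceiling}")
        if score == 1:
            return TFN.crisp(1.0)
        lo = max(score - self.delta, 1.0)
        hi = min(score + self.delta, self.ceiling)
        return TFN(lo, score, hi)

    def fuzzify_ratio(self, value: float) -> TFN:
        """Fuzzify an arbitrary positive ratio with spread ``delta``.

        Values >= 1 get ``(max(v - delta, 1), v, min(v + delta, ceiling))``
        mirroring the integer-score mapping; values < 1 are fuzzified on
        their reciprocal and inverted, keeping the map reciprocal-consistent.
        """
        if value <= 0:
            raise ValueError("judgment ratios must be positive")
        if value >= 1:
            lo = max(value - self.delta, 1.0)
            hi = max(min(value + self.delta, self.ceiling), value)
            return TFN(lo, value, hi)
        return tfn_invert(self.fuzzify_ratio(1.0 / value))


def scale_to_tfn(score: float, scale: FuzzyScale | None = None) -> TFN:
    """TFN for a 9-point score or its reciprocal.

    Admissible scores are the integers 1..9 and the fractions 1/2..1/9
    (floats within 1e-9 of these are accepted).
    """
    scale = scale or FuzzyScale()
    frac = Fraction(score).limit_denominator(1000)
    if frac.denominator == 1 and 1 <= frac.numerator <= 9:
        return scale.tfn(float(frac))
    if frac.numerator == 1 and 2 <= frac.denominator <= 9:
        return tfn_invert(scale.tfn(float(frac.denominator)))
    # tolerate floating representations of 1/3, 1/6, 1/7, 1/9
    for s in range(2, 10):
        if abs(score - 1.0 / s) <= 1e-9:
            return tfn_invert(scale.tfn(float(s)))
    raise ValueError(
        f"score {score} is not an admissible 9-point judgment (1..9 or 1/2..1/9)"
    )


class FuzzyComparisonMatrix:
    """Square reciprocal matrix of TFNs for one comparison question.

    Parameters
    ----------
    labels:
        Ordered names of the compared elements.
    entries:
        ``n x n`` nested sequence of :class:`TFN` (or ``(l, m, u)`` triples).
    context:
        The control criterion the comparison is made "with regard to".
    """

    def __init__(
        self,
        labels: Sequence[str],
        entries: Sequence[Sequence[TFN | Sequence[float]]],
        context: str | None = None,
    ) -> None:
        labels = list(labels)
        n = len(labels)
        if n < 2:
            raise ValueError("a comparison matrix needs at least 2 elements")
        if len(set(labels)) != n:
            raise ValueError("element labels must be unique")
        if len(entries) != n or any(len(row) != n for row in entries):
            raise ValueError(f"entries must form an {n}x{n} grid")
        grid: list[list[TFN]] = []
        for row in entries:
            grid.append([e if isinstance(e, TFN) else TFN(*e) for e in row])
        self.labels = labels
        self.entries = grid
        self.context = context

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, ij: tuple[int, int]) -> TFN:
        i, j = ij
        return self.entries[i][j]

    @classmethod
    def from_upper_triangle(
        cls,
        labels: Sequence[str],
        upper: Mapping[tuple[int, int], TFN],
        context: str | None = None,
    ) -> "FuzzyComparisonMatrix":
        """Build a reciprocal matrix from its strict upper triangle."""
        n = len(labels)
        one = TFN.crisp(1.0)
        grid = [[one for _ in range(n)] for _ in range(n)]
        for (i, j), t in upper.items():
            if not i < j:
                raise ValueError("upper-triangle keys require i < j")
            grid[i][j] = t
            grid[j][i] = tfn_invert(t)
        return cls(labels, grid, context=context)

    @classmethod
    def from_crisp(
        cls, labels: Sequence[str], matrix: np.ndarray, context: str | None = None
    ) -> "FuzzyComparisonMatrix":
        """Wrap a crisp positive reciprocal matrix as degenerate TFNs."""
        a = np.asarray(matrix, dtype=float)
        grid = [[TFN.crisp(a[i, j]) for j in range(a.shape[1])] for i in range(a.shape[0])]
        return cls(labels, grid, context=context)

    def to_array(self) -> np.ndarray:
        """Dense ``(n, n, 3)`` array of (l, m, u) components."""
        return np.array([[list(t) for t in row] for row in self.entries])

    def modal_matrix(self) -> np.ndarray:
        """Crisp matrix of modal values ``m_ij``."""
        return self.to_array()[:, :, 1]

    def bounds_geomean_matrix(self) -> np.ndarray:
        """Crisp matrix of ``sqrt(l_ij * u_ij)``."""
        a = self.to_array()
        return np.sqrt(a[:, :, 0] * a[:, :, 2])


@dataclass(frozen=True)
class ReciprocityReport:
    """Outcome of a reciprocity validation pass."""

    passed: bool
    max_deviation: float
    worst_cell: tuple[int, int] | None
    tol: float
    offending_cells: tuple[tuple[int, int], ...] = ()


def validate_reciprocal(
    matrix: FuzzyComparisonMatrix, tol: float = 1e-9
) -> ReciprocityReport:
    """Check the unit diagonal and ``a_ji == invert(a_ij)`` up to ``tol``.

    Reports the maximum componentwise deviation over all mirrored pairs and
    the worst offending cell; raises on structural violations (non-unit
    diagonal) so malformed input never reaches the numerics.
    """
    n = matrix.n
    bad_diag = [
        (i, i)
        for i in range(n)
        if not matrix[i, i].approx_equal(TFN.crisp(1.0), tol=max(tol, 1e-9))
    ]
    if bad_diag:
        raise ValueError(f"diagonal entries must be (1,1,1); offending cells {bad_diag}")
    worst = 0.0
    worst_cell: tuple[int, int] | None = None
    offenders: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            expect = tfn_invert(matrix[i, j])
            got = matrix[j, i]
            dev = max(
                abs(got.l - expect.l), abs(got.m - expect.m), abs(got.u - expect.u)
            )
            if dev > worst:
                worst, worst_cell = dev, (j, i)
            if dev > tol:
                offenders.append((j, i))
    return ReciprocityReport(
        passed=not offenders,
        max_deviation=worst,
        worst_cell=worst_cell,
        tol=tol,
        offending_cells=tuple(offenders),
    )


def aggregate_panel(
    matrices: Sequence[FuzzyComparisonMatrix],
) -> FuzzyComparisonMatrix:
    """Aggregate expert matrices cell by cell with the TFN geometric mean.

    All experts carry equal weight.  The geometric mean commutes with the
    fuzzy reciprocal, so the aggregate of reciprocal matrices is reciprocal
    by construction — the property the arithmetic mean would destroy.
    """
    if not matrices:
        raise ValueError("aggregate_panel requires at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.labels != first.labels:
            raise ValueError(
                f"mismatched labels across experts: {m.labels} vs {first.labels}"
            )
    n = first.n
    grid = [
        [tfn_geomean([m[i, j] for m in matrices]) for j in range(n)]
        for i in range(n)
    ]
    return FuzzyComparisonMatrix(first.labels, grid, context=first.context)


@dataclass
class ExpertPanel:
    """Per-expert comparison matrices keyed by comparison question.

    ``matrices[question]`` is the list of expert matrices (same labels and
    ordering for every expert) for that question.
    """

    matrices: dict[str, list[FuzzyComparisonMatrix]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = {len(v) for v in self.matrices.values()}
        if len(sizes) > 1:
            raise ValueError("every question must be answered by the same panel")
        for q, mats in self.matrices.items():
            labels = mats[0].labels
            for m in mats[1:]:
                if m.labels != labels:
                    raise ValueError(f"question {q!r}: experts disagree on element order")

    @property
    def n_experts(self) -> int:
        return len(next(iter(self.matrices.values()))) if self.matrices else 0

    @property
    def questions(self) -> list[str]:
        return list(self.matrices)

    def aggregate(self) -> dict[str, FuzzyComparisonMatrix]:
        """Geometric-mean aggregate matrix per question."""
        return {q: aggregate_panel(mats) for q, mats in self.matrices.items()}
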