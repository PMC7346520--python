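"""Local priority derivation from comparison matrices, with consistency checks.

Three derivation routes are exposed:

* ``buckley`` — Buckley's fuzzy geometric mean: row geometric means
  ``r_i``, fuzzy weights ``w_i = r_i (*) (sum_k r_k)^(-1)``, then
  defuzzification (default Liou–Wang total integral, alpha = 0.5).  This is
  the package default.
* ``extent`` — Chang's extent analysis on the fuzzy synthetic extents
  ``S_i`` with pairwise degrees of possibility; retained because it is
  widely cited, but it can assign exact zero weight to an element whose
  extent does not overlap the others, so it is not the default.
* ``eigenvector`` — classic principal right eigenvector of a crisp matrix
  by power iteration, with Saaty's lambda_max / CI / CR diagnostics.

Consistency of a fuzzy matrix is summarized by two crisp surrogates: CRm on
the matrix of modal values and CRg on the matrix of sqrt(l*u).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fuzzy import TFN, defuzzify, tfn_geomean, tfn_invert
from .judgments import FuzzyComparisonMatrix, validate_reciprocal

__all__ = [
    "SAATY_RI",
    "FuzzyWeightVector",
    "PriorityVector",
    "ConsistencyReport",
    "buckley_fuzzy_weights",
    "defuzzify_weights",
    "chang_extent_weights",
    "principal_eigenvector",
    "consistency_ratio",
    "fuzzy_cr_variants",
    "possibility_degree",
]

#: Saaty's random consistency indices by matrix order.
SAATY_RI: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}

CR_ACCEPT_THRESHOLD = 0.1


@dataclass
class FuzzyWeightVector:
    """Row geometric means and fuzzy weights from a fuzzy comparison matrix."""

    labels: list[str]
    row_geomeans: list[TFN]
    fuzzy_weights: list[TFN]


def _rank(values: np.ndarray) -> list[int]:
    # rank 1 = largest; ties broken stably by input (label) order
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    ranks = [0] * len(values)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


@dataclass
class PriorityVector:
    """Crisp local priorities: defuzzified ("certain") and normalized weights."""

    labels: list[str]
    certain: np.ndarray
    normal: np.ndarray
    ranks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.certain = np.asarray(self.certain, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if not self.ranks:
            self.ranks = _rank(self.normal)

    @classmethod
    def from_certain(cls, labels: Sequence[str], certain: np.ndarray) -> "PriorityVector":
        certain = np.asarray(certain, dtype=float)
        total = certain.sum()
        if total <= 0:
            raise ValueError("cannot normalize: weights sum to zero")
        return cls(list(labels), certain, certain / total)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.normal))


@dataclass(frozen=True)
class ConsistencyReport:
    """Saaty consistency diagnostics for one crisp comparison matrix."""

    lambda_max: float
    ci: float
    cr: float
    ri: float
    n: int
    variant: str = "plain"  # plain | modal | bounds_geomean

    @property
    def accepted(self) -> bool:
        return self.cr < CR_ACCEPT_THRESHOLD


def buckley_fuzzy_weights(matrix: FuzzyComparisonMatrix) -> FuzzyWeightVector:
    """Buckley's fuzzy geometric-mean weights.

    ``r_i`` is the componentwise geometric mean of row ``i``;
    ``w_i = r_i (*) invert(sum_k r_k)`` where the sum is componentwise and
    ``invert`` reverses the bounds.  The fuzzy weights therefore span the
    plausible range of each normalized priority.
    """
    n = matrix.n
    r = [tfn_geomean([matrix[i, j] for j in range(n)]) for i in range(n)]
    total = r[0]
    for t in r[1:]:
        total = total + t
    inv_total = tfn_invert(total)
    w = [ri * inv_total for ri in r]
    return FuzzyWeightVector(list(matrix.labels), r, w)


def defuzzify_weights(
    fw: FuzzyWeightVector, alpha: float = 0.5, method: str = "total_integral"
) -> PriorityVector:
    """Defuzzify fuzzy weights into certain weights and normalize.

    ``certain_i = defuzzify(w_i)``; ``normal_i = certain_i / sum certain``.
    Ranks are assigned by descending normalized weight (1 = highest), ties
    broken by input order.
    """
    certain = np.array([defuzzify(w, method=method, alpha=alpha) for w in fw.fuzzy_weights])
    return PriorityVector.from_certain(fw.labels, certain)


def possibility_degree(a: TFN, b: TFN) -> float:
    """Degree of possibility ``V(a >= b)`` for triangular extents.

    1 when ``a``'s mode dominates; 0 when the supports do not overlap
    (``b.l >= a.u``); otherwise the ordinate of the intersection of the
    falling edge of ``a`` with the rising edge of ``b``.
    """
    if a.m >= b.m:
        return 1.0
    if b.l >= a.u:
        return 0.0
    return (b.l - a.u) / ((a.m - a.u) - (b.m - b.l))


def chang_extent_weights(matrix: FuzzyComparisonMatrix) -> PriorityVector:
    """Chang's extent-analysis weights.

    Synthetic extents ``S_i = (sum_j a_ij) (*) invert(sum_ij a_ij)``;
    ``d_i = min_{j != i} V(S_i >= S_j)``; weights are the normalized
    ``d_i``.  Elements whose extent lies strictly below every other extent
    receive exact zero weight — a documented property of the method, not a
    defect of the implementation.
    """
    n = matrix.n
    row_sums = []
    for i in range(n):
        s = matrix[i, 0]
        for j in range(1, n):
            s = s + matrix[i, j]
        row_sums.append(s)
    grand = row_sums[0]
    for s in row_sums[1:]:
        grand = grand + s
    inv_grand = tfn_invert(grand)
    extents = [s * inv_grand for s in row_sums]
    d = np.array(
        [
            min(possibility_degree(extents[i], extents[j]) for j in range(n) if j != i)
            if n > 1
            else 1.0
            for i in range(n)
        ]
    )
    if d.sum() <= 0:
        raise ValueError(
            "extent analysis degenerated: every element has possibility degree 0"
        )
    pv = PriorityVector.from_certain(list(matrix.labels), d)
    return pv


def principal_eigenvector(
    matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> tuple[np.ndarray, float]:
    """Principal right eigenvector of a positive matrix by power iteration.

    Returns the eigenvector normalized to sum 1 and ``lambda_max`` estimated
    as the mean of the componentwise Rayleigh ratios ``(A w)_i / w_i``.
    Convergence is declared when successive normalized iterates differ by
    less than ``tol`` in the max norm.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(a <= 0):
        raise ValueError("comparison matrices must be strictly positive")
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = a @ w
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            w = nxt
            break
        w = nxt
    else:
        raise RuntimeError(
            f"power iteration did not converge within {max_iter} iterations "
            f"(last residual {np.max(np.abs(a @ w / (a @ w).sum() - w)):.3e})"
        )
    lambda_max = float(np.mean((a @ w) / w))
    return w, lambda_max


def consistency_ratio(
    matrix: np.ndarray,
    ri_table: Mapping[int, float] | None = None,
    variant: str = "plain",
) -> ConsistencyReport:
    """Saaty CI/CR for a crisp positive reciprocal matrix.

    ``CI = (lambda_max - n)/(n - 1)`` for n >= 2; ``CR = CI / RI(n)`` for
    n >= 3 and 0 for n <= 2 (matrices of order <= 2 are always consistent).
    Judgments are accepted when CR < 0.1.
    """
    ri_table = ri_table if ri_table is not None else SAATY_RI
    a = np.asarray(matrix, dtype=float)
    n = a.shape[0]
    if n == 1:
        return ConsistencyReport(1.0, 0.0, 0.0, 0.0, 1, variant)
    _, lam = principal_eigenvector(a)
    ci = (lam - n) / (n - 1)
    if n <= 2:
        return ConsistencyReport(lam, 0.0, 0.0, 0.0, n, variant)
    if n not in ri_table:
        raise KeyError(f"no random index configured for matrix order n={n}")
    ri = ri_table[n]
    cr = ci / ri
    return ConsistencyReport(lam, ci, cr, ri, n, variant)


def fuzzy_cr_variants(
    matrix: FuzzyComparisonMatrix, ri_table: Mapping[int, float] | None = None
) -> tuple[ConsistencyReport, ConsistencyReport]:
    """CR of a fuzzy matrix via two crisp surrogates.

    ``CRm`` uses the matrix of modal values; ``CRg`` uses the matrix of
    geometric means of the lower and upper bounds, ``sqrt(l * u)``.  For a
    crisp-degenerate matrix both coincide with the plain CR.
    """
    validate_reciprocal(matrix, tol=np.inf)  # structural check only
    crm = consistency_ratio(matrix.modal_matrix(), ri_table, variant="modal")
    crg = consistency_ratio(
        matrix.bounds_geomean_matrix(), ri_table, variant="bounds_geomean"
    )
    return crm, crg


def derive_priorities(
    matrix: FuzzyComparisonMatrix,
    method: str = "buckley",
    alpha: float = 0.5,
) -> PriorityVector:
    """Dispatch to one of the derivation routes by name."""
    if method == "buckley":
        return defuzzify_weights(buckley_fuzzy_weights(matrix), alpha=alpha)
    if method == "extent":
        return chang_extent_weights(matrix)
    if method == "eigenvector":
        w, _ = principal_eigenvector(matrix.modal_matrix())
        return PriorityVector.from_certain(list(matrix.labels), w)
    raise ValueError(f"unknown derivation method {method!r}")
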