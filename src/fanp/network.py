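"""ANP network model, supermatrix assembly, weighting, limit and synthesis.

An ANP model is a set of clusters of elements connected by directed
dependence edges (inner edges stay within a cluster, outer edges cross
clusters), optionally controlled by a goal node.  Local priority vectors —
one per (source element, target cluster) dependence — are stacked into a
block supermatrix whose column for element ``e`` holds, in the rows of
cluster ``C``, the priorities of ``C``'s elements with respect to ``e``.

Cluster-level weights make the supermatrix column-stochastic (the weighted
supermatrix); raising it to powers until the columns stop changing yields
the limit supermatrix, whose columns carry the global priorities — the
Markov-chain stationary distribution of the influence network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .priority import PriorityVector, _rank

__all__ = [
    "Cluster",
    "Dependency",
    "ANPNetwork",
    "ClusterMatrix",
    "Supermatrix",
    "SynthesisResult",
    "assemble_supermatrix",
    "default_cluster_matrix",
    "weight_supermatrix",
    "limit_supermatrix",
    "synthesize_priorities",
]

GOAL_CLUSTER = "__goal__"


@dataclass(frozen=True)
class Cluster:
    name: str
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"cluster {self.name!r} has no elements")


@dataclass(frozen=True)
class Dependency:
    """Directed influence edge: judgments about ``target_cluster``'s elements
    are made with regard to ``source`` (an element, a cluster, or the goal)."""

    source: str
    target_cluster: str
    kind: str = "outer"  # inner | outer


class ANPNetwork:
    """Clusters, elements, dependence edges and an optional goal node.

    The goal, when present, is represented internally as a single-element
    cluster placed first in the element ordering.
    """

    def __init__(
        self,
        clusters: Sequence[Cluster],
        dependencies: Sequence[Dependency],
        goal: str | None = None,
    ) -> None:
        self.goal = goal
        self.clusters = list(clusters)
        names = [c.name for c in self.clusters]
        if len(set(names)) != len(names):
            raise ValueError("cluster names must be unique")
        all_elements = [e for c in self.clusters for e in c.elements]
        if goal is not None:
            all_elements = [goal] + all_elements
        if len(set(all_elements)) != len(all_elements):
            raise ValueError("element names must be globally unique")
        self._cluster_by_name = {c.name: c for c in self.clusters}
        self.dependencies = list(dependencies)
        for d in self.dependencies:
            if d.target_cluster not in self._cluster_by_name:
                raise ValueError(f"dependency targets unknown cluster {d.target_cluster!r}")
            if not (
                d.source == goal
                or d.source in self._cluster_by_name
                or any(d.source in c.elements for c in self.clusters)
            ):
                raise ValueError(f"dependency source {d.source!r} is not a known node")

    # -- orderings -------------------------------------------------------
    @property
    def element_order(self) -> list[str]:
        """Deterministic ordering: goal first, then clusters in declaration order."""
        out = [self.goal] if self.goal is not None else []
        for c in self.clusters:
            out.extend(c.elements)
        return out

    @property
    def cluster_order(self) -> list[str]:
        out = [GOAL_CLUSTER] if self.goal is not None else []
        out.extend(c.name for c in self.clusters)
        return out

    def cluster_of(self, element: str) -> str:
        if element == self.goal:
            return GOAL_CLUSTER
        for c in self.clusters:
            if element in c.elements:
                return c.name
        raise KeyError(element)

    def cluster_elements(self, name: str) -> tuple[str, ...]:
        if name == GOAL_CLUSTER:
            return (self.goal,) if self.goal else ()
        return self._cluster_by_name[name].elements

    def edges_by_source_element(self) -> list[tuple[str, str]]:
        """Expand cluster-level sources to their member elements.

        Returns the (source element, target cluster) pairs for which a local
        priority vector is required.
        """
        pairs: list[tuple[str, str]] = []
        for d in self.dependencies:
            if d.source == self.goal or any(
                d.source in c.elements for c in self.clusters
            ):
                sources = [d.source]
            else:  # cluster-level edge
                sources = list(self._cluster_by_name[d.source].elements)
            for s in sources:
                if (s, d.target_cluster) not in pairs:
                    pairs.append((s, d.target_cluster))
        return pairs


@dataclass
class ClusterMatrix:
    """Cluster-level weights; column = controlling (source) cluster."""

    labels: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("cluster matrix shape must match its labels")
        if np.any(self.weights < 0):
            raise ValueError("cluster weights must be non-negative")
        sums = self.weights.sum(axis=0)
        bad = [
            self.labels[j]
            for j in range(n)
            if sums[j] > 0 and abs(sums[j] - 1.0) > 1e-9
        ]
        if bad:
            raise ValueError(f"nonzero cluster-matrix columns must sum to 1: {bad}")

    def weight(self, target_cluster: str, source_cluster: str) -> float:
        i = self.labels.index(target_cluster)
        j = self.labels.index(source_cluster)
        return float(self.weights[i, j])


@dataclass
class Supermatrix:
    """Block matrix over the network's element ordering."""

    labels: list[str]
    matrix: np.ndarray
    stage: str  # unweighted | weighted | limit
    cluster_slices: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("supermatrix shape must match its labels")

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]

    def is_column_stochastic(self, tol: float = 1e-9) -> bool:
        sums = self.matrix.sum(axis=0)
        return all(s <= tol or abs(s - 1.0) <= tol for s in sums)


@dataclass
class SynthesisResult:
    """Global element priorities with the cluster-level roll-up."""

    element_labels: list[str]
    overall: np.ndarray
    element_ranks: list[int]
    cluster_labels: list[str]
    cluster_priorities: np.ndarray
    cluster_ranks: list[int]
    within_cluster: dict[str, dict[str, float]]

    def as_records(self) -> list[dict]:
        """Flat rows mirroring a final-weights table."""
        rows = []
        for cname, cw, crank in zip(
            self.cluster_labels, self.cluster_priorities, self.cluster_ranks
        ):
            within = self.within_cluster[cname]
            for el, ww in within.items():
                i = self.element_labels.index(el)
                rows.append(
                    {
                        "cluster": cname,
                        "element": el,
                        "within_cluster_weight": ww,
                        "element_rank": self.element_ranks[i],
                        "overall_weight": float(self.overall[i]),
                        "cluster_weight": float(cw),
                        "cluster_rank": crank,
                    }
                )
        return rows


def _cluster_slices(network: ANPNetwork) -> dict[str, list[int]]:
    order = network.element_order
    return {
        cname: [order.index(e) for e in network.cluster_elements(cname)]
        for cname in network.cluster_order
    }


def assemble_supermatrix(
    network: ANPNetwork,
    local_priorities: Mapping[tuple[str, str], PriorityVector],
) -> Supermatrix:
    """Stack local priority vectors into the unweighted supermatrix.

    For every dependence pair ``(source element e, target cluster C)`` the
    rows of ``C`` in column ``e`` receive the normalized local priorities of
    ``C``'s elements with respect to ``e``; blocks with no dependence stay
    zero.  Raises when a declared edge has no vector or the vector's labels
    do not match the target cluster.
    """
    order = network.element_order
    idx = {e: i for i, e in enumerate(order)}
    n = len(order)
    m = np.zeros((n, n))
    for source, target in network.edges_by_source_element():
        key = (source, target)
        if key not in local_priorities:
            raise KeyError(
                f"no local priority vector supplied for dependence {source!r} -> "
                f"cluster {target!r}"
            )
        pv = local_priorities[key]
        target_elements = list(network.cluster_elements(target))
        if sorted(pv.labels) != sorted(target_elements):
            raise ValueError(
                f"vector for {source!r} -> {target!r} has labels {pv.labels}, "
                f"expected the cluster elements {target_elements}"
            )
        j = idx[source]
        for label, value in zip(pv.labels, pv.normal):
            m[idx[label], j] = value
    return Supermatrix(order, m, "unweighted", _cluster_slices(network))


def default_cluster_matrix(network: ANPNetwork) -> ClusterMatrix:
    """Equal cluster weights over each source cluster's influenced clusters.

    A stand-in for an elicited cluster-comparison matrix: every cluster that
    receives influence from a source cluster gets the same weight in that
    source's column.
    """
    labels = network.cluster_order
    n = len(labels)
    w = np.zeros((n, n))
    targets_by_source: dict[str, set[str]] = {c: set() for c in labels}
    for source, target in network.edges_by_source_element():
        targets_by_source[network.cluster_of(source)].add(target)
    for j, src in enumerate(labels):
        targets = sorted(targets_by_source[src])
        for t in targets:
            w[labels.index(t), j] = 1.0 / len(targets)
    return ClusterMatrix(labels, w)


def weight_supermatrix(
    sm: Supermatrix, cm: ClusterMatrix, sink_policy: str = "zero"
) -> Supermatrix:
    """Scale each block by its cluster weight and renormalize the columns.

    Column ``j`` (an element of source cluster ``S``) has its rows in target
    cluster ``T`` multiplied by the cluster weight of ``T`` under ``S``;
    each nonzero column is then renormalized to sum exactly 1, giving the
    column-stochastic weighted supermatrix.

    ``sink_policy`` decides what happens to all-zero columns (elements with
    no outgoing influence): ``"zero"`` leaves them zero (the default, which
    makes pure hierarchies nilpotent — see :func:`limit_supermatrix`);
    ``"uniform"`` replaces them with a uniform column, the convention some
    ANP tools use to keep the chain fully stochastic.
    """
    if sink_policy not in ("zero", "uniform"):
        raise ValueError(f"sink_policy must be 'zero' or 'uniform', got {sink_policy!r}")
    if sm.stage != "unweighted":
        raise ValueError(f"expected an unweighted supermatrix, got stage {sm.stage!r}")
    slices = sm.cluster_slices
    m = sm.matrix.copy()
    col_cluster = {}
    for cname, rows in slices.items():
        for i in rows:
            col_cluster[i] = cname
    for j in range(m.shape[1]):
        src = col_cluster[j]
        for tname, rows in slices.items():
            scale = cm.weight(tname, src)
            m[rows, j] = m[rows, j] * scale
        total = m[:, j].sum()
        if sm.matrix[:, j].sum() > 0 and total <= 0:
            raise ValueError(
                f"column {sm.labels[j]!r} lost all mass: its nonzero blocks have "
                "zero cluster weight"
            )
        if total > 0:
            m[:, j] /= total
        elif sink_policy == "uniform":
            m[:, j] = 1.0 / m.shape[0]
    return Supermatrix(sm.labels, m, "weighted", slices)


def _nonzero_columns_stochastic(m: np.ndarray, tol: float = 1e-9) -> bool:
    sums = m.sum(axis=0)
    return all(s <= tol or abs(s - 1.0) <= tol for s in sums)


def limit_supermatrix(
    sm: Supermatrix, tol: float = 1e-9, max_squarings: int = 64
) -> Supermatrix:
    """Limit of the weighted supermatrix under repeated powers.

    Repeated squaring (equivalent in the limit to raising to any large odd
    power) until the entries stop changing.  Two non-generic cases are
    handled explicitly:

    * nilpotent chains (hierarchies with zero sink columns): squaring would
      reach the all-zero matrix; the last nonzero power is returned instead,
      which holds exactly the accumulated top-down weight products;
    * periodic chains: when the squaring fixed point ``P`` is not a genuine
      one-step limit, the Cesàro average of ``P, P A, P A^2, ...`` over the
      detected cycle is returned.
    """
    if sm.stage != "weighted":
        raise ValueError(f"expected a weighted supermatrix, got stage {sm.stage!r}")
    a = sm.matrix
    if not _nonzero_columns_stochastic(a, tol=1e-6):
        raise ValueError("weighted supermatrix must be column-stochastic on nonzero columns")
    b = a.copy()
    residuals: list[float] = []
    for _ in range(max_squarings):
        c = b @ b
        if np.max(np.abs(c)) < tol and np.max(np.abs(b)) >= tol:
            # nilpotent (hierarchy) case: b is the last nonzero power
            return Supermatrix(sm.labels, b, "limit", sm.cluster_slices)
        resid = float(np.max(np.abs(c - b)))
        residuals.append(resid)
        b = c
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"limit supermatrix did not converge in {max_squarings} squarings; "
            f"residual history tail {residuals[-5:]}"
        )
    # b is a fixed point of squaring; average over the one-step cycle so a
    # periodic chain returns its Cesaro limit rather than one phase of it
    cycle = [b]
    nxt = b @ a
    guard = 0
    while np.max(np.abs(nxt - b)) > max(tol, 1e-12) * 10:
        cycle.append(nxt)
        nxt = nxt @ a
        guard += 1
        if guard > a.shape[0] + 1:
            raise RuntimeError("no cycle detected after squaring converged")
    limit = np.mean(cycle, axis=0) if len(cycle) > 1 else b
    return Supermatrix(sm.labels, limit, "limit", sm.cluster_slices)


def synthesize_priorities(limit: Supermatrix, network: ANPNetwork) -> SynthesisResult:
    """Read global priorities off the limit supermatrix.

    The goal's limit column (or the common column when all nonzero columns
    agree) restricted to the element rows, renormalized to sum 1, gives the
    overall element priorities.  Cluster priorities are the sums over their
    elements; within-cluster weights renormalize each cluster block.
    """
    if limit.stage != "limit":
        raise ValueError(f"expected a limit supermatrix, got stage {limit.stage!r}")
    order = limit.labels
    if network.goal is not None:
        col = limit.column(network.goal)
    else:
        m = limit.matrix
        nz = [j for j in range(m.shape[1]) if m[:, j].sum() > 0]
        if not nz:
            raise ValueError("limit supermatrix is identically zero")
        col = m[:, nz[0]]
        for j in nz[1:]:
            ref = col / col.sum()
            other = m[:, j] / m[:, j].sum()
            if np.max(np.abs(ref - other)) > 1e-6:
                raise ValueError(
                    "limit columns disagree; the network has no common limit column"
                )
    element_rows = [i for i, e in enumerate(order) if e != network.goal]
    mass = col[element_rows].sum()
    if mass <= 0:
        raise ValueError("zero total mass on element rows of the limit column")
    element_labels = [order[i] for i in element_rows]
    overall = col[element_rows] / mass

    cluster_labels = [c.name for c in network.clusters]
    cluster_pr = []
    within: dict[str, dict[str, float]] = {}
    for c in network.clusters:
        idxs = [element_labels.index(e) for e in c.elements]
        cw = float(overall[idxs].sum())
        cluster_pr.append(cw)
        within[c.name] = {
            e: (float(overall[i]) / cw if cw > 0 else 0.0)
            for e, i in zip(c.elements, idxs)
        }
    cluster_pr_arr = np.array(cluster_pr)
    return SynthesisResult(
        element_labels=element_labels,
        overall=overall,
        element_ranks=_rank(overall),
        cluster_labels=cluster_labels,
        cluster_priorities=cluster_pr_arr,
        cluster_ranks=_rank(cluster_pr_arr),
        within_cluster=within,
    )
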