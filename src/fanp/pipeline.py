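"""End-to-end orchestration: load, aggregate, derive, check, synthesize.

The pipeline mirrors the four methodological steps of a fuzzy-ANP study:

1. model establishment — a network of clusters, elements and dependencies;
2. fuzzy pairwise comparison and defuzzification — per-expert matrices are
   aggregated by geometric mean and turned into crisp local priorities;
3. supermatrix formation — local vectors are stacked, cluster-weighted to
   column-stochastic form, and raised to powers until the columns converge;
4. decision evaluation — every comparison is gated on CR < 0.1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import datasets
from .io import (
    CLUSTER_TARGET,
    load_judgments,
    load_network,
    parse_question,
)
from .judgments import ExpertPanel, FuzzyComparisonMatrix, FuzzyScale, validate_reciprocal
from .network import (
    ANPNetwork,
    ClusterMatrix,
    Supermatrix,
    SynthesisResult,
    assemble_supermatrix,
    default_cluster_matrix,
    limit_supermatrix,
    synthesize_priorities,
    weight_supermatrix,
)
from .priority import (
    ConsistencyReport,
    PriorityVector,
    buckley_fuzzy_weights,
    defuzzify_weights,
    derive_priorities,
    fuzzy_cr_variants,
)

__all__ = [
    "RunConfig",
    "Report",
    "ConsistencyGateError",
    "ReproductionError",
    "load_inputs",
    "run_pipeline",
    "reproduce_worked_example",
]


class ConsistencyGateError(RuntimeError):
    """A comparison failed the CR < 0.1 acceptance rule."""


class ReproductionError(RuntimeError):
    """The worked example did not reproduce its expected values."""


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one place."""

    network_path: str | Path
    judgments_path: str | Path
    method: str = "buckley"  # buckley | extent | eigenvector
    defuzzify_method: str = "total_integral"
    alpha: float = 0.5
    scale_delta: float = 1.0  # TFN spread used to fuzzify crisp 9-point scores
    reciprocity_tol: float = 1e-6
    sink_policy: str = "zero"
    limit_tol: float = 1e-9
    force: bool = False  # proceed past CR >= 0.1

    def provenance(self) -> dict:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"config": payload, "config_hash": digest}


@dataclass
class Report:
    """Full audit trail of one pipeline run."""

    network: ANPNetwork
    aggregates: dict[str, FuzzyComparisonMatrix]
    local_priorities: dict[str, PriorityVector]
    consistency: dict[str, tuple[ConsistencyReport, ConsistencyReport]]
    cluster_matrix: ClusterMatrix
    supermatrices: dict[str, Supermatrix]  # unweighted | weighted | limit
    synthesis: SynthesisResult
    provenance: dict = field(default_factory=dict)

    def consistency_table(self) -> list[dict]:
        rows = []
        for q, (crm, crg) in self.consistency.items():
            rows.append(
                {
                    "question": q,
                    "lambda_max_modal": crm.lambda_max,
                    "CRm": crm.cr,
                    "CRg": crg.cr,
                    "RI": crm.ri,
                    "accepted": crm.accepted,
                }
            )
        return rows


def load_inputs(config: RunConfig) -> tuple[ANPNetwork, ExpertPanel]:
    """Load and structurally validate the network and the judgment panel."""
    network = load_network(config.network_path)
    panel = load_judgments(
        config.judgments_path, scale=FuzzyScale(delta=config.scale_delta)
    )
    errors = []
    cluster_names = set(network.cluster_order)
    for q, mats in panel.matrices.items():
        source, target = parse_question(q)
        if target != CLUSTER_TARGET and target not in cluster_names:
            errors.append(f"question {q!r}: unknown target cluster {target!r}")
            continue
        expected = (
            set(c.name for c in network.clusters)
            if target == CLUSTER_TARGET
            else set(network.cluster_elements(target))
        )
        got = set(mats[0].labels)
        if not got <= expected:
            errors.append(
                f"question {q!r}: labels {sorted(got - expected)} are not "
                f"elements of {target!r}"
            )
        for k, m in enumerate(mats):
            rep = validate_reciprocal(m, tol=config.reciprocity_tol)
            if not rep.passed:
                errors.append(
                    f"question {q!r}, expert #{k + 1}: reciprocity violated at "
                    f"cells {rep.offending_cells} (max deviation {rep.max_deviation:.2e})"
                )
    if errors:
        raise ValueError("invalid inputs:\n  " + "\n  ".join(errors))
    return network, panel


def _cluster_matrix_from_questions(
    network: ANPNetwork,
    vectors: Mapping[str, PriorityVector],
) -> ClusterMatrix:
    """Cluster matrix from '@clusters' questions, defaults elsewhere."""
    cm = default_cluster_matrix(network)
    labels = cm.labels
    w = cm.weights.copy()
    for q, pv in vectors.items():
        source, target = parse_question(q)
        if target != CLUSTER_TARGET:
            continue
        src_cluster = (
            source
            if source in labels
            else network.cluster_of(source)
        )
        j = labels.index(src_cluster)
        w[:, j] = 0.0
        for name, value in zip(pv.labels, pv.normal):
            w[labels.index(name), j] = value
    return ClusterMatrix(labels, w)


def run_pipeline(config: RunConfig) -> Report:
    """Run the full fuzzy-ANP pipeline described in the module docstring.

    Raises :class:`ConsistencyGateError` when any aggregated comparison has
    a modal-matrix CR >= 0.1, unless ``config.force`` is set.
    """
    network, panel = load_inputs(config)
    aggregates = panel.aggregate()

    consistency = {}
    rejected = []
    for q, agg in aggregates.items():
        crm, crg = fuzzy_cr_variants(agg)
        consistency[q] = (crm, crg)
        if not crm.accepted:
            rejected.append(f"{q} (CRm={crm.cr:.3f})")
    if rejected and not config.force:
        raise ConsistencyGateError(
            "comparisons rejected by the CR < 0.1 rule: " + "; ".join(rejected)
        )

    local = {
        q: derive_priorities(agg, method=config.method, alpha=config.alpha)
        for q, agg in aggregates.items()
    }

    element_vectors = {}
    for q, pv in local.items():
        source, target = parse_question(q)
        if target != CLUSTER_TARGET:
            element_vectors[(source, target)] = pv
    unweighted = assemble_supermatrix(network, element_vectors)
    cm = _cluster_matrix_from_questions(network, local)
    weighted = weight_supermatrix(unweighted, cm, sink_policy=config.sink_policy)
    limit = limit_supermatrix(weighted, tol=config.limit_tol)
    synthesis = synthesize_priorities(limit, network)
    return Report(
        network=network,
        aggregates=aggregates,
        local_priorities=local,
        consistency=consistency,
        cluster_matrix=cm,
        supermatrices={"unweighted": unweighted, "weighted": weighted, "limit": limit},
        synthesis=synthesis,
        provenance=config.provenance(),
    )


# expected worked-example outputs, printed at 3 decimals
_EXPECTED_CERTAIN = {"Efficiency": 0.168, "Equity and Access": 0.428, "Effectiveness": 0.413}
_EXPECTED_NORMAL = {"Efficiency": 0.166, "Equity and Access": 0.424, "Effectiveness": 0.409}


def reproduce_worked_example(alpha: float = 0.5) -> dict:
    """Re-derive the bundled worked example and check it to 3 decimals.

    Runs the fuzzy geometric-mean weight derivation and total-integral
    defuzzification on the bundled 3x3 paradigm comparison, plus both CR
    surrogates, and verifies the certain and normalized weights against
    their published printed values.  Returns a report fragment with full-
    precision numbers; raises :class:`ReproductionError` on any mismatch.
    """
    matrix = datasets.paradigm_comparison_matrix()
    fw = buckley_fuzzy_weights(matrix)
    pv = defuzzify_weights(fw, alpha=alpha)
    crm, crg = fuzzy_cr_variants(matrix)
    mismatches = []
    for label, certain, normal in zip(pv.labels, pv.certain, pv.normal):
        if round(certain, 3) != _EXPECTED_CERTAIN[label]:
            mismatches.append(
                f"{label}: certain {certain:.6f} != expected {_EXPECTED_CERTAIN[label]}"
            )
        if round(normal, 3) != _EXPECTED_NORMAL[label]:
            mismatches.append(
                f"{label}: normal {normal:.6f} != expected {_EXPECTED_NORMAL[label]}"
            )
    if mismatches:
        raise ReproductionError(
            "worked example did not reproduce:\n  " + "\n  ".join(mismatches)
        )
    return {
        "labels": pv.labels,
        "fuzzy_weights": [list(w) for w in fw.fuzzy_weights],
        "certain": [float(x) for x in pv.certain],
        "normal": [float(x) for x in pv.normal],
        "ranks": pv.ranks,
        "CRm": {"cr": crm.cr, "lambda_max": crm.lambda_max, "ri": crm.ri, "accepted": crm.accepted},
        "CRg": {"cr": crg.cr, "lambda_max": crg.lambda_max, "ri": crg.ri, "accepted": crg.accepted},
    }
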