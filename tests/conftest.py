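import numpy as np
import pytest

from fanp import ExpertPanel, datasets
from fanp.io import CLUSTER_TARGET, format_question, save_judgments, save_network
from fanp.network import ANPNetwork, Cluster, Dependency
from fanp.simulate import consistent_matrix_from_weights, fuzzify_crisp_matrix


@pytest.fixture(scope="session")
def paradigm_matrix():
    """The bundled 3x3 fuzzy aggregate paradigm comparison."""
    return datasets.paradigm_comparison_matrix()


@pytest.fixture(scope="session")
def hierarchy_scenario():
    """Three-cluster allocation hierarchy with a known ground truth.

    Cluster weights and within-cluster element weights mirror the magnitudes
    of the emulated study; overall ground truth is their product.
    """
    clusters = [
        Cluster("Efficiency", ("Total population", "Non-resident patient")),
        Cluster(
            "Equity and Access",
            ("Health professionals", "Bed occupancy", "Prescriptions"),
        ),
        Cluster(
            "Effectiveness",
            ("Endemic burden", "Rare disease burden", "Trauma burden"),
        ),
    ]
    goal = "Scarce drug allocation"
    network = ANPNetwork(
        clusters, [Dependency(goal, c.name) for c in clusters], goal=goal
    )
    cluster_w = np.array([0.37, 0.459, 0.171])
    cluster_w = cluster_w / cluster_w.sum()
    within = [
        np.array([0.6942, 0.3058]),
        np.array([0.1727, 0.3833, 0.4440]),
        np.array([0.3418, 0.3754, 0.2828]),
    ]
    within = [w / w.sum() for w in within]
    overall = np.concatenate([cw * w for cw, w in zip(cluster_w, within)])
    return {
        "network": network,
        "clusters": clusters,
        "goal": goal,
        "cluster_weights": cluster_w,
        "within": within,
        "overall": overall,
    }


def make_hierarchy_panel(scenario, n_experts=3, delta=0.0):
    """Zero-noise expert panel answering every hierarchy question."""
    mats = {}
    goal = scenario["goal"]
    for cluster, w in zip(scenario["clusters"], scenario["within"]):
        q = format_question(goal, cluster.name)
        base = consistent_matrix_from_weights(w)
        mats[q] = [
            fuzzify_crisp_matrix(base, delta, labels=list(cluster.elements), context=q)
            for _ in range(n_experts)
        ]
    q = format_question(goal, CLUSTER_TARGET)
    base = consistent_matrix_from_weights(scenario["cluster_weights"])
    mats[q] = [
        fuzzify_crisp_matrix(
            base, delta, labels=[c.name for c in scenario["clusters"]], context=q
        )
        for _ in range(n_experts)
    ]
    return ExpertPanel(matrices=mats)


@pytest.fixture
def hierarchy_run(tmp_path, hierarchy_scenario):
    """Hierarchy scenario written to disk, ready for run_pipeline."""
    panel = make_hierarchy_panel(hierarchy_scenario)
    net_path = tmp_path / "network.yaml"
    judg_path = tmp_path / "judgments.csv"
    save_network(hierarchy_scenario["network"], net_path)
    save_judgments(panel, judg_path)
    return {"network_path": net_path, "judgments_path": judg_path, **hierarchy_scenario}
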