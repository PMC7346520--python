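"""Reading and writing the package's file formats.

* network configs — YAML/JSON with ``clusters``, ``dependencies`` and an
  optional ``goal``;
* judgment tables — long-format CSV with one row per matrix cell, either
  fuzzy (``expert,question,row,col,l,m,u``) or crisp 9-point
  (``expert,question,row,col,score``); a question is written
  ``"<source> -> <target cluster>"``, with the special target
  ``"@clusters"`` for cluster-level comparisons;
* fuzzy matrices — long-format CSV ``row,col,l,m,u``;
* bundled fixtures for the worked example (see :mod:`fanp.datasets`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .fuzzy import TFN
from .judgments import ExpertPanel, FuzzyComparisonMatrix, FuzzyScale, scale_to_tfn
from .network import ANPNetwork, Cluster, Dependency
from .priority import PriorityVector

__all__ = [
    "CLUSTER_TARGET",
    "load_network",
    "load_fuzzy_matrix_csv",
    "save_fuzzy_matrix_csv",
    "load_judgments",
    "save_judgments",
    "parse_question",
    "format_question",
    "save_priority_vector",
]

#: Question target marking a cluster-level (cluster matrix) comparison.
#: (not "#...": "#" is the comment character in the CSV formats)
CLUSTER_TARGET = "@clusters"
_QUESTION_SEP = " -> "


def load_network(path: str | Path) -> ANPNetwork:
    """Load an :class:`ANPNetwork` from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    try:
        clusters = [
            Cluster(c["name"], tuple(c["elements"])) for c in cfg["clusters"]
        ]
        deps = [
            Dependency(d["source"], d["target_cluster"], d.get("kind", "outer"))
            for d in cfg.get("dependencies", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed network config ({exc})") from exc
    return ANPNetwork(clusters, deps, goal=cfg.get("goal"))


def load_fuzzy_matrix_csv(
    path: str | Path, context: str | None = None
) -> FuzzyComparisonMatrix:
    """Read a single fuzzy matrix from long-format CSV ``row,col,l,m,u``."""
    df = pd.read_csv(path, comment="#")
    labels = list(dict.fromkeys(df["row"]))
    cells = {
        (r.row, r.col): TFN(r.l, r.m, r.u) for r in df.itertuples(index=False)
    }
    missing = [
        (a, b) for a in labels for b in labels if (a, b) not in cells
    ]
    if missing:
        raise ValueError(f"{path}: incomplete matrix, missing cells {missing}")
    grid = [[cells[(a, b)] for b in labels] for a in labels]
    return FuzzyComparisonMatrix(labels, grid, context=context)


def save_fuzzy_matrix_csv(matrix: FuzzyComparisonMatrix, path: str | Path) -> None:
    rows = [
        {
            "row": matrix.labels[i],
            "col": matrix.labels[j],
            "l": matrix[i, j].l,
            "m": matrix[i, j].m,
            "u": matrix[i, j].u,
        }
        for i in range(matrix.n)
        for j in range(matrix.n)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def format_question(source: str, target_cluster: str) -> str:
    return f"{source}{_QUESTION_SEP}{target_cluster}"


def parse_question(question: str) -> tuple[str, str]:
    """Split ``"<source> -> <target cluster>"`` into its two parts."""
    if _QUESTION_SEP not in question:
        raise ValueError(
            f"question {question!r} is not of the form '<source> -> <target cluster>'"
        )
    source, target = question.split(_QUESTION_SEP, 1)
    return source.strip(), target.strip()


def load_judgments(
    path: str | Path,
    scale: FuzzyScale | None = None,
) -> ExpertPanel:
    """Read an expert panel from a long-format judgments CSV.

    Fuzzy input needs columns ``expert,question,row,col,l,m,u``; crisp
    9-point input needs ``expert,question,row,col,score`` and is fuzzified
    through ``scale`` (default spread 1).  Only the upper triangle (plus any
    redundant rows, which are checked later by reciprocity validation) needs
    to be present for each question; missing mirror cells are filled by TFN
    inversion, truly absent pairs are an error naming the cell.
    """
    df = pd.read_csv(path, comment="#")
    fuzzy = {"l", "m", "u"}.issubset(df.columns)
    if not fuzzy and "score" not in df.columns:
        raise ValueError(f"{path}: need columns l,m,u or score")
    scale = scale or FuzzyScale()
    matrices: dict[str, list[FuzzyComparisonMatrix]] = {}
    experts = list(dict.fromkeys(df["expert"]))
    questions = list(dict.fromkeys(df["question"]))
    for q in questions:
        dq = df[df["question"] == q]
        labels = list(dict.fromkeys(list(dq["row"]) + list(dq["col"])))
        per_expert = []
        for e in experts:
            de = dq[dq["expert"] == e]
            cells: dict[tuple[str, str], TFN] = {}
            for r in de.itertuples(index=False):
                t = TFN(r.l, r.m, r.u) if fuzzy else scale_to_tfn(r.score, scale)
                cells[(r.row, r.col)] = t
            grid = []
            for a in labels:
                row = []
                for b in labels:
                    if a == b:
                        row.append(TFN.crisp(1.0))
                    elif (a, b) in cells:
                        row.append(cells[(a, b)])
                    elif (b, a) in cells:
                        row.append(cells[(b, a)].inverse())
                    else:
                        raise ValueError(
                            f"{path}: expert {e!r}, question {q!r}: missing "
                            f"judgment for cell ({a!r}, {b!r})"
                        )
                grid.append(row)
            per_expert.append(FuzzyComparisonMatrix(labels, grid, context=q))
        matrices[q] = per_expert
    return ExpertPanel(matrices=matrices, metadata={"path": str(path)})


def save_judgments(panel: ExpertPanel, path: str | Path) -> None:
    """Write a panel as fuzzy long-format CSV (upper triangle only)."""
    rows = []
    for q, mats in panel.matrices.items():
        for e, m in enumerate(mats, start=1):
            for i in range(m.n):
                for j in range(i + 1, m.n):
                    t = m[i, j]
                    rows.append(
                        {
                            "expert": f"expert{e:02d}",
                            "question": q,
                            "row": m.labels[i],
                            "col": m.labels[j],
                            "l": t.l,
                            "m": t.m,
                            "u": t.u,
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)


def save_priority_vector(pv: PriorityVector, path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": pv.labels,
            "certain": pv.certain,
            "normal": pv.normal,
            "rank": pv.ranks,
        }
    ).to_csv(path, index=False)


def network_to_dict(network: ANPNetwork) -> Mapping:
    return {
        "goal": network.goal,
        "clusters": [
            {"name": c.name, "elements": list(c.elements)} for c in network.clusters
        ],
        "dependencies": [
            {"source": d.source, "target_cluster": d.target_cluster, "kind": d.kind}
            for d in network.dependencies
        ],
    }


def save_network(network: ANPNetwork, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(network_to_dict(network)), sort_keys=False))
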