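"""Bundled worked-example fixtures.

Three small text fixtures ship with the package:

* the 3x3 fuzzy aggregate comparison of the allocation paradigms
  (Efficiency, Equity and Access, Effectiveness) with regard to the goal —
  the package's reproduction target;
* the scarce-drug allocation network (3 clusters, 8 indicators, goal);
  its edge list is a documented reconstruction, see the file header;
* the reported final weights of the source study, for side-by-side
  comparison only (they depend on elicited supermatrices that are not part
  of the bundled inputs and are not recomputed here).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import load_fuzzy_matrix_csv, load_network
from .judgments import FuzzyComparisonMatrix
from .network import ANPNetwork

__all__ = [
    "paradigm_comparison_matrix",
    "allocation_network",
    "reference_final_weights",
]

_DATA = resources.files("fanp") / "data"


def paradigm_comparison_matrix() -> FuzzyComparisonMatrix:
    """The fuzzy aggregate paradigm comparison (the worked example input)."""
    with resources.as_file(_DATA / "worked_example_matrix.csv") as p:
        return load_fuzzy_matrix_csv(p, context="Scarce drug allocation")


def allocation_network() -> ANPNetwork:
    """The scarce-drug allocation network (reconstructed edge set)."""
    with resources.as_file(_DATA / "allocation_network.yaml") as p:
        return load_network(p)


def reference_final_weights() -> pd.DataFrame:
    """Reported final weights (reference only, not a recomputation target)."""
    with resources.as_file(_DATA / "reference_final_weights.csv") as p:
        return pd.read_csv(p, comment="#")
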