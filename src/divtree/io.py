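"""Readers/writers for mutation-annotated trees and analysis results.

Trees travel as Newick with the branch-length field carrying the *integer*
mutation count (calendar time is latent and never serialized).  Fits are
written as JSON with full provenance; landscapes and LRT tables as TSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import FitResult, LRTResult
from .tree import ReconTree

logger = logging.getLogger(__name__)

__all__ = [
    "read_mutation_tree",
    "write_mutation_tree",
    "write_fit_result",
    "read_fit_result_json",
    "write_landscape",
    "write_lrt_table",
    "write_truth_table",
]

LRT_COLUMNS = ["clade", "lambda_LR", "p_value", "q_main", "mu_main", "q_sub", "mu_sub"]


def read_mutation_tree(path: str | Path) -> ReconTree:
    """Read a Newick tree whose branch lengths are mutation counts.

    Non-integer lengths are rounded to the nearest integer (with a logged
    warning); negative lengths are an error; multifurcations are resolved to
    binary with zero-mutation branches.
    """
    import dendropy

    dtree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=False
    )
    return ReconTree.from_dendropy(dtree)


def write_mutation_tree(tree: ReconTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def _provenance(extra: dict | None = None) -> dict:
    from . import __version__

    prov = {"divtree_version": __version__, "numpy_version": np.__version__}
    if extra:
        prov.update(extra)
    return prov


def write_fit_result(
    result: FitResult, path: str | Path, provenance: dict | None = None
) -> None:
    payload = {
        "model": result.settings.get("model", "division"),
        "params": dataclasses.asdict(result.params),
        "log_likelihood": result.log_likelihood,
        "converged": result.converged,
        "settings": result.settings,
        "n_evaluations": len(result.trace),
        "provenance": _provenance(provenance),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fit_result_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_landscape(
    matrix: np.ndarray, q_values, mu_values, path: str | Path
) -> pd.DataFrame:
    """Long-format TSV with one row per (q, mu) grid point."""
    q_values = np.asarray(q_values, float)
    mu_values = np.asarray(mu_values, float)
    qq, mm = np.meshgrid(q_values, mu_values, indexing="ij")
    df = pd.DataFrame(
        {"q": qq.ravel(), "mu": mm.ravel(), "log_likelihood": np.asarray(matrix).ravel()}
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_lrt_table(
    results: list[LRTResult], path: str | Path, accepted: list[LRTResult] | None = None
) -> pd.DataFrame:
    """LRT table with one column set per tested clade scenario."""
    rows = []
    accepted_ids = {id(r) for r in (accepted or [])}
    for r in results:
        rows.append(
            {
                "clade": r.focal_clade,
                "lambda_LR": r.lambda_lr,
                "p_value": r.p_value,
                "q_main": r.main.params.q,
                "mu_main": r.main.mu,
                "q_sub": r.distinct.params.q,
                "mu_sub": r.distinct.mu,
                "bonferroni_significant": id(r) in accepted_ids
                if accepted is not None
                else pd.NA,
            }
        )
    df = pd.DataFrame(rows, columns=LRT_COLUMNS + ["bonferroni_significant"])
    if accepted is None:
        df = df[LRT_COLUMNS]
    df.to_csv(path, sep="\t", index=False)
    return df


def write_messages(messages: dict, path: str | Path) -> pd.DataFrame:
    """Debug dump of per-branch DP messages: branch id, grid node, log value."""
    rows = {
        "branch": np.concatenate(
            [np.full(m.grid.nodes.size, b) for b, m in messages.items()]
        ),
        "tau": np.concatenate([m.grid.nodes for m in messages.values()]),
        "log_value": np.concatenate([m.log_values for m in messages.values()]),
    }
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_truth_table(tree: ReconTree, path: str | Path) -> pd.DataFrame:
    """Per-branch simulator ground truth (duration, hidden divisions)."""
    if tree.durations is None or tree.hidden_births is None:
        raise ValueError("tree carries no truth annotations")
    df = pd.DataFrame(
        {
            "node": np.arange(1, tree.n_nodes),
            "parent": tree.parent[1:],
            "is_leaf": [tree.is_leaf(v) for v in range(1, tree.n_nodes)],
            "mutations": tree.mutations[1:],
            "duration": tree.durations[1:],
            "hidden_births": tree.hidden_births[1:],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
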