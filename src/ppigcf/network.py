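"""Correlation-weighted interaction networks and isolated-gene elimination.

Second pipeline layer. Within each GO group the interaction weight between
two genes is the product of their expression Pearson correlation and their
annotation similarity; an edge exists when the weight reaches ``tau_ppi``.
Genes with no edge at all ("isolated interaction genes") are eliminated,
leaving the RD1 survivor set.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PPINetwork, StageResult
from .corr_filter import pearson_matrix

log = logging.getLogger(__name__)

DEFAULT_TAU_PPI = 0.5


def weight_matrix(group_expr: ExpressionMatrix, sim: np.ndarray) -> np.ndarray:
    """W = PCC(expression) * sim, element-wise, with a zero diagonal.

    Zero-variance genes have undefined correlation; their rows/columns are 0
    (logged by :func:`ppigcf.corr_filter.pearson_matrix`).
    """
    k = group_expr.n_genes
    if sim.shape != (k, k):
        raise ValueError(
            f"sim shape {sim.shape} does not match group size {k}"
        )
    r = pearson_matrix(group_expr)
    W = r * sim
    np.fill_diagonal(W, 0.0)
    return W


def build_network(
    W: np.ndarray, tau_ppi: float, group_term: str, nodes: list[str]
) -> PPINetwork:
    """Threshold W into an undirected graph: edge iff W[a][b] >= tau_ppi."""
    if not 0.0 < tau_ppi <= 1.0:
        raise ValueError(f"tau_ppi must be in (0, 1], got {tau_ppi}")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    ii, jj = np.where(np.triu(W, k=1) >= tau_ppi)
    for i, j in zip(ii, jj):
        g.add_edge(nodes[i], nodes[j], weight=float(W[i, j]))
    return PPINetwork(
        group_term=group_term, nodes=list(nodes), weights=W,
        tau_ppi=tau_ppi, graph=g,
    )


def eliminate_isolated(net: PPINetwork) -> StageResult:
    """RD1: keep genes with degree >= 1, drop degree-0 nodes as ISOLATED."""
    degrees = {n: net.graph.degree(n) for n in net.nodes}
    kept = {n for n, d in degrees.items() if d >= 1}
    eliminated = {n: "ISOLATED" for n, d in degrees.items() if d == 0}
    scores = pd.DataFrame(
        {"degree": pd.Series(degrees, dtype=float)}
    ).sort_index()
    return StageResult(stage="RD1", kept=kept, eliminated=eliminated,
                       scores=scores)


def export_edge_list(net: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, d in sorted(net.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['weight']:.6g}\n")
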