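"""Information-content scoring and the final gene selection.

Fourth pipeline layer. Each RD2 gene is scored by the binary entropy of its
neighbourhood split inside its connected component of the surviving-pair
graph: x_b is the fraction of the component the gene is directly linked to,
x_b* the complement, and IC = (1/lambda) * (x_b log2 x_b + x_b* log2 x_b*)
with lambda = -1 by default, i.e. the entropy H(x_b) in [0, 1]. Genes whose
IC strictly exceeds the threshold delta form the final reduced dataset
(FRD). delta defaults to the equal-weight mean of a packaged 6x4 table of
IC thresholds from six GO-analysis methods (ABP, AMF, ACC, MBP, MMF, MCC)
under four CESSM metrics (ECC, RES, Seq, Pfam).

Specificity (depth of the gene's deepest annotated term, log-scaled against
the ontology maximum) and coverage (one minus the descendant fraction of
that term) multiply into the CET diagnostic; CET, the conflict and acute-
similarity values are reported but play no role in selection.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GOAnnotationSet, ICTable, StageResult
from .errors import BadLambdaError, GeneNotInGraphError, NoDepthError

log = logging.getLogger(__name__)

DEFAULT_LAMBDA = -1.0

GOA_METHODS = ("ABP", "AMF", "ACC", "MBP", "MMF", "MCC")
GOA_METRICS = ("ECC", "RES", "Seq", "Pfam")

#: Packaged IC thresholds of the six GO-analysis methods x four CESSM metrics.
DEFAULT_GOA_TABLE = pd.DataFrame(
    [
        [0.5949, 0.9762, 0.5765, 0.6726],
        [0.7293, 0.9076, 0.4679, 0.4648],
        [0.6549, 0.9371, 0.4960, 0.3741],
        [0.6443, 0.9605, 0.5703, 0.6502],
        [0.6754, 0.8966, 0.4171, 0.4311],
        [0.6875, 0.9110, 0.4725, 0.3512],
    ],
    index=list(GOA_METHODS),
    columns=list(GOA_METRICS),
)


def load_goa_table(path) -> pd.DataFrame:
    """Read a methods x metrics threshold table from TSV (first column =
    method name, header = metric names); values must lie in [0, 1]."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: incomplete threshold table")
    if ((values < 0) | (values > 1)).any():
        raise ValueError(f"{path}: thresholds must lie in [0, 1]")
    return table


def ic_threshold(table: pd.DataFrame = DEFAULT_GOA_TABLE) -> float:
    """Equal-weight mean of all table cells."""
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("incomplete threshold table")
    return float(values.mean())


def _deepest_term(gene: str, annos: GOAnnotationSet) -> tuple[str, int]:
    terms = [
        t for t in annos.annotations.get(gene, set()) if t in annos.depth
    ]
    if not terms:
        raise NoDepthError(f"gene {gene!r} has no term with a defined depth")
    # deepest annotated term; ties resolve to the smallest GO ID
    best = min(terms, key=lambda t: (-annos.depth[t], t))
    return best, annos.depth[best]


def specificity(gene: str, annos: GOAnnotationSet) -> float:
    """log(d_g + 1) / log(D_max + 1): deeper annotation -> closer to 1."""
    _, d_g = _deepest_term(gene, annos)
    d_max = max(annos.depth.values())
    if d_max == 0:
        return 0.0
    return math.log(d_g + 1) / math.log(d_max + 1)


def coverage(gene: str, annos: GOAnnotationSet) -> float:
    """1 - (descendants of the deepest annotated term) / (other terms).

    General terms (many descendants) approach 0, leaves are exactly 1.
    """
    term, _ = _deepest_term(gene, annos)
    n_terms = len(annos.hierarchy.nodes)
    if n_terms <= 1:
        return 1.0
    return 1.0 - annos.n_descendants[term] / (n_terms - 1)


def cet(spec: float, cov: float) -> float:
    return spec * cov


def bipartition_frequencies(
    gene: str, graph: nx.Graph
) -> tuple[float, float]:
    """Within-component neighbour vs non-neighbour frequencies of ``gene``.

    f_B = degree inside the connected component, f_B* = non-neighbour
    members of the component; returns the complementary relative
    frequencies (x_b, x_b*).
    """
    if gene not in graph:
        raise GeneNotInGraphError(f"gene {gene!r} not in graph")
    comp = nx.node_connected_component(graph, gene)
    f_b = graph.degree(gene)
    f_b_star = (len(comp) - 1) - f_b
    total = f_b + f_b_star
    if total == 0:  # singleton component
        return 1.0, 0.0
    x_b = f_b / total
    return x_b, 1.0 - x_b


def information_content(
    x_b: float, x_b_star: float, lambda_: float = DEFAULT_LAMBDA
) -> float:
    """(1/lambda) * (x_b log2 x_b + x_b* log2 x_b*), with 0 log 0 = 0.

    lambda = -1 yields the binary entropy, in [0, 1] and maximal at 0.5.
    """
    if lambda_ == 0:
        raise BadLambdaError("lambda must be nonzero")
    s = 0.0
    for p in (x_b, x_b_star):
        if p > 0:
            s += p * math.log2(p)
    return s / lambda_


def acute_similarity_diagnostics(
    x_b: float, x_b_star: float
) -> tuple[float, float | None]:
    """Report-only conflict / acute-similarity diagnostics.

    c_diag = d/dx [x(1-x)] at x_b = 1 - 2 x_b. as_diag = 1 + log2(p log2 p)
    with p = x_b * x_b*, defined only when p log2 p > 0 (else None).
    """
    c_diag = 1.0 - 2.0 * x_b
    p = x_b * x_b_star
    as_diag = None
    if p > 0:
        inner = p * math.log2(p)
        if inner > 0:
            as_diag = 1.0 + math.log2(inner)
    return c_diag, as_diag


def build_ic_table(
    genes,
    graph: nx.Graph,
    annos: GOAnnotationSet,
    lambda_: float = DEFAULT_LAMBDA,
    delta: float | None = None,
    goa_table: pd.DataFrame = DEFAULT_GOA_TABLE,
    score_mode: str = "ic",
) -> ICTable:
    """Score every gene of a group's RD2 set on its surviving-pair graph."""
    if score_mode not in ("ic", "cet_times_ic"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    if delta is None:
        delta = ic_threshold(goa_table)
    rows = []
    for g in sorted(genes):
        x_b, x_b_star = bipartition_frequencies(g, graph)
        ic = information_content(x_b, x_b_star, lambda_)
        try:
            sp = specificity(g, annos)
            cov = coverage(g, annos)
        except NoDepthError:
            log.warning("gene %s has no depth; CET undefined", g)
            sp = cov = float("nan")
        c_diag, as_diag = acute_similarity_diagnostics(x_b, x_b_star)
        score = ic if score_mode == "ic" else cet(sp, cov) * ic
        rows.append(
            {
                "gene": g,
                "specificity": sp,
                "coverage": cov,
                "cet": cet(sp, cov),
                "x_b": x_b,
                "x_b_star": x_b_star,
                "ic": ic,
                "score": score,
                "c_diag": c_diag,
                "as_diag": np.nan if as_diag is None else as_diag,
            }
        )
    cols = ["specificity", "coverage", "cet", "x_b", "x_b_star", "ic",
            "score", "c_diag", "as_diag"]
    table = (
        pd.DataFrame(rows).set_index("gene")[cols]
        if rows
        else pd.DataFrame(columns=cols)
    )
    return ICTable(table=table, lambda_=lambda_, delta=float(delta))


def select_significant(ic_table: ICTable, delta: float | None = None) -> StageResult:
    """FRD: keep genes whose score strictly exceeds delta."""
    if delta is None:
        delta = ic_table.delta
    kept = set(ic_table.table.index[ic_table.table["score"] > delta])
    eliminated = {
        g: "LOW_IC" for g in ic_table.table.index if g not in kept
    }
    return StageResult(stage="FRD", kept=kept, eliminated=eliminated,
                       scores=ic_table.table[["ic", "score"]].copy())
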