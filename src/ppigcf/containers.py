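"""Core in-memory containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import NotTwoClassesError, UnknownSampleError

#: Elimination reason codes, in stage order.
REASONS = ("UNMAPPED", "ISOLATED", "NEGATIVE_PCC", "WEAK_CORRELATION", "LOW_IC")

STAGES = ("GROUPED", "RD1", "RD2", "FRD")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression table with optional two-class labels.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample IDs
    as columns. Labels, when present, cover every sample and take exactly two
    distinct values.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        return ExpressionMatrix(self.values.loc[list(genes)], self.labels)

    def attach_labels(self, labels: pd.Series) -> None:
        """Join a per-sample label mapping onto this matrix.

        Raises UNKNOWN_SAMPLE if a matrix sample has no label and
        NOT_TWO_CLASSES if the joined labels are not exactly two classes.
        """
        missing = [s for s in self.samples if s not in labels.index]
        if missing:
            raise UnknownSampleError(f"no label for sample(s): {missing[:5]}")
        joined = labels.reindex(self.samples)
        if joined.nunique() != 2:
            raise NotTwoClassesError(
                f"expected 2 classes, found {joined.nunique()}"
            )
        self.labels = joined

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")


@dataclass
class GOAnnotationSet:
    """Gene -> GO-term annotations plus the term hierarchy.

    ``hierarchy`` is a child -> parent DiGraph (edges point rootward).
    ``depth`` is the shortest-path distance from the namespace root,
    ``n_descendants`` counts distinct terms reachable downward (self
    excluded), and ``term_ic`` is the annotation-frequency information
    content normalised to (0, 1].
    """

    annotations: dict[str, set[str]] = field(default_factory=dict)
    aspects: dict[tuple[str, str], str] = field(default_factory=dict)
    hierarchy: nx.DiGraph = field(default_factory=nx.DiGraph)
    namespace: dict[str, str] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)
    n_descendants: dict[str, int] = field(default_factory=dict)
    term_ic: dict[str, float] = field(default_factory=dict)
    orphans: set[str] = field(default_factory=set)

    @property
    def terms(self) -> set[str]:
        return set(self.hierarchy.nodes)

    def genes_annotated(self) -> set[str]:
        return {g for g, ts in self.annotations.items() if ts}

    def descendants(self, term: str) -> set[str]:
        """Distinct terms reachable downward from ``term`` (self excluded)."""
        if term not in self.hierarchy:
            return set()
        # hierarchy edges point child -> parent, so descendants are ancestors
        # in the graph sense
        return set(nx.ancestors(self.hierarchy, term))

    def merge_annotations(self, other: "GOAnnotationSet") -> "GOAnnotationSet":
        """Combine the annotation part of ``other`` with this hierarchy."""
        merged = GOAnnotationSet(
            annotations={g: set(t) for g, t in other.annotations.items()},
            aspects=dict(other.aspects),
            hierarchy=self.hierarchy,
            namespace=self.namespace,
            depth=self.depth,
            n_descendants=self.n_descendants,
            term_ic=dict(self.term_ic),
        )
        merged.orphans = {
            t
            for ts in merged.annotations.values()
            for t in ts
            if t not in merged.hierarchy
        }
        return merged


@dataclass
class StageResult:
    """Outcome of one elimination stage.

    ``kept`` and ``eliminated`` partition the stage's input gene set;
    ``scores`` holds whatever per-gene numbers the stage computed.
    """

    stage: str
    kept: set[str]
    eliminated: dict[str, str]
    scores: pd.DataFrame | None = None

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        overlap = self.kept & set(self.eliminated)
        if overlap:
            raise ValueError(f"genes both kept and eliminated: {overlap}")

    @property
    def input_genes(self) -> set[str]:
        return self.kept | set(self.eliminated)


@dataclass
class GOGroup:
    """One anchor-term gene group with its pairwise similarity matrix."""

    group_term: str
    members: list[str]
    sim: np.ndarray | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PPINetwork:
    """Correlation-weighted interaction graph for one group."""

    group_term: str
    nodes: list[str]
    weights: np.ndarray
    tau_ppi: float
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def adjacency(self) -> dict[str, set[str]]:
        return {n: set(self.graph.neighbors(n)) for n in self.nodes}


@dataclass
class CorrelationTables:
    """Per-group correlation-filter matrices (gene x gene, aligned)."""

    genes: list[str]
    r: np.ndarray
    R2: np.ndarray
    ll: np.ndarray
    sem: np.ndarray
    mu_g: float


@dataclass
class ICTable:
    """Per-gene information-content scores and the selection threshold."""

    table: pd.DataFrame  # specificity, coverage, cet, x_b, x_b_star, ic, ...
    lambda_: float
    delta: float
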