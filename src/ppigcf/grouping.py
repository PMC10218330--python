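"""Gene -> GO mapping, anchor-term grouping and group similarity matrices.

The first pipeline layer. Genes are mapped onto their GO annotations, then
partitioned into disjoint groups anchored at a configurable list of (mostly
cellular-component) target terms. A gene joins a group when it is annotated
to the anchor itself or to any descendant of it; when several anchors match,
the deepest one wins, ties broken by the lexicographically smallest GO ID, so
assignment is a total deterministic order. Each group carries a gene-gene
similarity matrix built from annotation-frequency information content.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .containers import ExpressionMatrix, GOAnnotationSet, GOGroup
from .errors import EmptyGroupsError

log = logging.getLogger(__name__)

#: Default anchor terms: the nine GO IDs of the most cancer-affected classes.
DEFAULT_TARGET_TERMS = (
    "GO:0003674",
    "GO:0005764",
    "GO:0005783",
    "GO:0005794",
    "GO:0005886",
    "GO:0008150",
    "GO:0016021",
    "GO:0005737",
    "GO:0015630",
)


def compute_term_ic(annos: GOAnnotationSet) -> dict[str, float]:
    """Annotation-frequency (corpus) information content per term, in (0, 1].

    freq(t) = (annotations to t or its descendants + 1) /
              (total annotations + number of terms)        (Laplace smoothing)
    ic(t)   = -log2 freq(t), normalised by the corpus maximum.
    """
    terms = sorted(annos.hierarchy.nodes)
    if not terms:
        return {}
    total_ann = sum(len(ts) for ts in annos.annotations.values())
    ann_per_term: dict[str, int] = {t: 0 for t in terms}
    for ts in annos.annotations.values():
        for t in ts:
            if t in ann_per_term:
                ann_per_term[t] += 1
    raw: dict[str, float] = {}
    denom = total_ann + len(terms)
    for t in terms:
        count = ann_per_term[t] + sum(
            ann_per_term[d] for d in annos.descendants(t)
        )
        raw[t] = -math.log2((count + 1) / denom)
    top = max(raw.values())
    if top <= 0:  # degenerate single-term corpus
        return {t: 1.0 for t in terms}
    return {t: raw[t] / top for t in terms}


def map_genes(
    matrix: ExpressionMatrix, annos: GOAnnotationSet
) -> tuple[dict[str, set[str]], list[str]]:
    """Split matrix genes into (annotated -> terms) and an unmapped list.

    Annotations for genes absent from the matrix are ignored (counted in the
    log only): the matrix defines the gene universe.
    """
    mapped: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for g in matrix.genes:
        terms = annos.annotations.get(g, set())
        if terms:
            mapped[g] = set(terms)
        else:
            unmapped.append(g)
    extra = sum(1 for g in annos.annotations if g not in set(matrix.genes))
    if extra:
        log.info("%d annotated gene(s) absent from the matrix; ignored", extra)
    return mapped, unmapped


def assign_groups(
    mapped: dict[str, set[str]],
    annos: GOAnnotationSet,
    target_terms=DEFAULT_TARGET_TERMS,
) -> tuple[list[GOGroup], list[str]]:
    """Partition mapped genes into one group per matching anchor term.

    Returns (groups, genes matching no anchor). Raises EMPTY_GROUPS when no
    gene is assigned anywhere.
    """
    targets = list(dict.fromkeys(target_terms))
    if not targets:
        raise ValueError("target_terms must be non-empty")
    # term -> anchors it activates (the anchor itself or any ancestor anchor)
    term_anchor: dict[str, set[str]] = {}
    for anchor in targets:
        term_anchor.setdefault(anchor, set()).add(anchor)
        for d in annos.descendants(anchor):
            term_anchor.setdefault(d, set()).add(anchor)
    members: dict[str, list[str]] = {t: [] for t in targets}
    unassigned: list[str] = []
    for g in sorted(mapped):
        anchors: set[str] = set()
        for t in mapped[g]:
            anchors |= term_anchor.get(t, set())
        if not anchors:
            unassigned.append(g)
            continue
        # deepest anchor wins; ties break to the smallest GO ID
        best = min(
            anchors, key=lambda a: (-annos.depth.get(a, 0), a)
        )
        members[best].append(g)
    groups = [
        GOGroup(group_term=t, members=members[t])
        for t in targets
        if members[t]
    ]
    if not groups:
        raise EmptyGroupsError("no gene matched any target term")
    return groups, unassigned


def group_similarity(group: GOGroup, annos: GOAnnotationSet) -> np.ndarray:
    """Pairwise similarity sim[i][j] = sqrt(a_i * a_j), unit diagonal.

    a_g is the gene's strongest (maximum) normalised term IC over its
    annotated terms in the group's namespace; annotated terms outside the
    hierarchy or the namespace fall back to the full annotation set.
    """
    ns = annos.namespace.get(group.group_term)
    a = np.zeros(group.size)
    for i, g in enumerate(group.members):
        terms = annos.annotations.get(g, set())
        in_ns = [
            t for t in terms
            if t in annos.term_ic and annos.namespace.get(t) == ns
        ]
        pool = in_ns or [t for t in terms if t in annos.term_ic]
        a[i] = max((annos.term_ic[t] for t in pool), default=0.0)
    sim = np.sqrt(np.outer(a, a))
    np.fill_diagonal(sim, 1.0)
    return sim


def build_groups(
    matrix: ExpressionMatrix,
    annos: GOAnnotationSet,
    target_terms=DEFAULT_TARGET_TERMS,
) -> tuple[list[GOGroup], dict[str, str]]:
    """Full grouping layer: map, assign, attach similarity matrices.

    Returns (groups with sim matrices, eliminated gene -> reason UNMAPPED).
    """
    if not annos.term_ic:
        annos.term_ic = compute_term_ic(annos)
    mapped, unmapped = map_genes(matrix, annos)
    groups, unassigned = assign_groups(mapped, annos, target_terms)
    for grp in groups:
        grp.sim = group_similarity(grp, annos)
    eliminated = {g: "UNMAPPED" for g in unmapped + unassigned}
    return groups, eliminated
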