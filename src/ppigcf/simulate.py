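"""Two-class expression simulator with planted, recoverable structure.

Each group carries one block of informative genes drawn from a common-factor
equicorrelation model (pairwise correlation ``rho``) with a between-class
mean shift of ``effect_size`` noise-SDs; blocks alternate between up- and
down-regulation so both directions occur, as in real disease signatures.
The remaining in-group genes are near-constant ("isolated": their
correlations vanish, so the network stage should drop them), and ``n_noise``
independent noise genes with no class effect are spread round-robin over the
groups. A small cellular-component ontology is built alongside: one root,
one anchor term per group at varied depth, and a private leaf term per
informative gene, so annotation-frequency IC separates specific from
generic annotations.

Expression sits on a log2-intensity-like scale around ``baseline`` so the
grand mean is positive (the semantic-similarity score divides by it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GOAnnotationSet
from .errors import BadConfigError
from .grouping import DEFAULT_TARGET_TERMS
from .io import write_expression, write_labels

CC_ROOT = "GO:0005575"

ROLES = ("INFORMATIVE", "NOISE", "ISOLATED")


@dataclass
class SimulationConfig:
    n_groups: int = 3
    genes_per_group: int = 60
    n_informative_per_group: int = 30
    n_noise: int = 300
    n_samples: int = 100
    rho: float = 0.9
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline: float = 8.0
    isolated_jitter: float = 1e-3
    ontology_depth: int = 5
    seed: int = 42

    def validate(self) -> None:
        if self.n_groups < 1 or self.n_groups > 9:
            raise BadConfigError("n_groups must be in 1..9")
        if self.n_informative_per_group > self.genes_per_group:
            raise BadConfigError(
                "n_informative_per_group exceeds genes_per_group"
            )
        if self.n_informative_per_group < 1:
            raise BadConfigError("need at least one informative gene")
        if self.n_samples < 2 or self.n_samples % 2:
            raise BadConfigError("n_samples must be even and >= 2")
        if not 0.0 < self.rho < 1.0:
            raise BadConfigError("rho must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise BadConfigError("noise_sd must be positive")
        if self.n_noise < 0:
            raise BadConfigError("n_noise must be non-negative")
        if self.ontology_depth < 3:
            raise BadConfigError("ontology_depth must be >= 3")


def _anchor_terms(n_groups: int) -> list[str]:
    return list(DEFAULT_TARGET_TERMS[:n_groups])


def _build_ontology(cfg: SimulationConfig, leaf_count: int):
    """Root, per-group anchors at varied depth, one leaf per informative gene.

    Returns (hierarchy DiGraph child->parent, namespace, anchor list,
    anchor -> list of leaf terms).
    """
    anchors = _anchor_terms(cfg.n_groups)
    hier = nx.DiGraph()
    hier.add_node(CC_ROOT)
    namespace = {CC_ROOT: "CC"}
    leaves: dict[str, list[str]] = {}
    filler_i = 0
    leaf_i = 0
    max_anchor_depth = max(1, cfg.ontology_depth - 1)
    for gi, anchor in enumerate(anchors):
        depth = 1 + gi % max_anchor_depth
        parent = CC_ROOT
        for _ in range(depth - 1):
            filler = f"GO:08{filler_i:05d}"
            filler_i += 1
            hier.add_edge(filler, parent)
            namespace[filler] = "CC"
            parent = filler
        hier.add_edge(anchor, parent)
        namespace[anchor] = "CC"
        leaves[anchor] = []
        for _ in range(cfg.n_informative_per_group):
            leaf = f"GO:07{leaf_i:05d}"
            leaf_i += 1
            hier.add_edge(leaf, anchor)
            namespace[leaf] = "CC"
            leaves[anchor].append(leaf)
    return hier, namespace, anchors, leaves


def generate(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, GOAnnotationSet, pd.DataFrame]:
    """Simulate (expression matrix with labels, annotation set, ground truth).

    The ground-truth frame has one row per gene: role (INFORMATIVE, NOISE or
    ISOLATED), group anchor term, and block ID (= group index here; each
    group holds a single correlated block).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    half = n // 2
    class_ind = np.array([0.0] * half + [1.0] * (n - half))
    samples = [f"s{i + 1:04d}" for i in range(n)]
    labels = pd.Series(
        ["class1"] * half + ["class2"] * (n - half), index=samples,
        name="label",
    )

    hier, namespace, anchors, leaves = _build_ontology(
        cfg, cfg.n_groups * cfg.n_informative_per_group
    )

    gene_rows: list[np.ndarray] = []
    names: list[str] = []
    truth_rows: list[dict] = []
    annotations: dict[str, set[str]] = {}
    gene_i = 0

    def new_gene() -> str:
        nonlocal gene_i
        gene_i += 1
        return f"g{gene_i:05d}"

    for gi, anchor in enumerate(anchors):
        sign = 1.0 if gi % 2 == 0 else -1.0
        z_block = rng.standard_normal(n)
        shift = sign * cfg.effect_size * cfg.noise_sd * class_ind
        for bi in range(cfg.n_informative_per_group):
            eps = rng.standard_normal(n)
            x = cfg.baseline + cfg.noise_sd * (
                np.sqrt(cfg.rho) * z_block + np.sqrt(1 - cfg.rho) * eps
            ) + shift
            g = new_gene()
            names.append(g)
            gene_rows.append(x)
            annotations[g] = {leaves[anchor][bi]}
            truth_rows.append(
                {"gene": g, "role": "INFORMATIVE", "group": anchor,
                 "block": gi}
            )
        for _ in range(cfg.genes_per_group - cfg.n_informative_per_group):
            x = cfg.baseline + cfg.isolated_jitter * cfg.noise_sd \
                * rng.standard_normal(n)
            g = new_gene()
            names.append(g)
            gene_rows.append(x)
            annotations[g] = {anchor}
            truth_rows.append(
                {"gene": g, "role": "ISOLATED", "group": anchor, "block": gi}
            )
    for i in range(cfg.n_noise):
        anchor = anchors[i % len(anchors)]
        x = cfg.baseline + cfg.noise_sd * rng.standard_normal(n)
        g = new_gene()
        names.append(g)
        gene_rows.append(x)
        annotations[g] = {anchor}
        truth_rows.append(
            {"gene": g, "role": "NOISE", "group": anchor,
             "block": i % len(anchors)}
        )

    values = pd.DataFrame(np.vstack(gene_rows), index=names, columns=samples)
    em = ExpressionMatrix(values)
    em.attach_labels(labels)

    depth = dict(
        nx.shortest_path_length(hier.reverse(copy=False), CC_ROOT)
    )
    n_desc = {t: len(nx.ancestors(hier, t)) for t in hier.nodes}
    annos = GOAnnotationSet(
        annotations=annotations,
        aspects={(g, t): "CC" for g, ts in annotations.items() for t in ts},
        hierarchy=hier,
        namespace=namespace,
        depth=depth,
        n_descendants=n_desc,
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return em, annos, truth


def write_fixture(
    em: ExpressionMatrix,
    annos: GOAnnotationSet,
    truth: pd.DataFrame,
    outdir,
) -> dict[str, Path]:
    """Write the simulated data in the exact dialects the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv"
             for name in ("expression", "labels", "annotations", "ontology",
                          "truth")}
    write_expression(em, paths["expression"])
    write_labels(em.labels, paths["labels"])
    with open(paths["annotations"], "w") as fh:
        fh.write("gene\tgo_id\taspect\n")
        for g in sorted(annos.annotations):
            for t in sorted(annos.annotations[g]):
                fh.write(f"{g}\t{t}\t{annos.aspects[(g, t)]}\n")
    with open(paths["ontology"], "w") as fh:
        fh.write("term\tparent\tnamespace\n")
        for t in sorted(annos.hierarchy.nodes):
            parents = sorted(annos.hierarchy.successors(t))
            if parents:
                for p in parents:
                    fh.write(f"{t}\t{p}\t{annos.namespace[t]}\n")
            else:
                fh.write(f"{t}\t\t{annos.namespace[t]}\n")
    truth.to_csv(paths["truth"], sep="\t")
    return paths
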