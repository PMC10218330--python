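import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ppigcf.containers import ExpressionMatrix, GOAnnotationSet
from ppigcf.simulate import SimulationConfig, generate


@pytest.fixture
def tiny_em():
    """4 genes x 4 samples with an exactly-correlated pair (g1, g2)."""
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],
            [4.0, 3.0, 2.0, 1.0],
            [5.0, 5.0, 5.0, 5.0],
        ],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3", "s4"],
    )
    em = ExpressionMatrix(values)
    em.attach_labels(
        pd.Series(["class1", "class1", "class2", "class2"],
                  index=values.columns)
    )
    return em


def make_annotation_set(edges, annotations, namespace="CC"):
    """Build a GOAnnotationSet from (child, parent) edges; parent None = root."""
    hier = nx.DiGraph()
    root = None
    for child, parent in edges:
        if parent is None:
            hier.add_node(child)
            root = child
        else:
            hier.add_edge(child, parent)
    depth = dict(nx.shortest_path_length(hier.reverse(copy=False), root))
    n_desc = {t: len(nx.ancestors(hier, t)) for t in hier.nodes}
    return GOAnnotationSet(
        annotations={g: set(ts) for g, ts in annotations.items()},
        aspects={(g, t): namespace for g, ts in annotations.items()
                 for t in ts},
        hierarchy=hier,
        namespace={t: namespace for t in hier.nodes},
        depth=depth,
        n_descendants=n_desc,
    )


@pytest.fixture
def chain_annos():
    """root <- a <- b with three genes annotated along the chain."""
    return make_annotation_set(
        edges=[("GO:0000001", None), ("GO:0000002", "GO:0000001"),
               ("GO:0000003", "GO:0000002")],
        annotations={"g1": {"GO:0000003"}, "g2": {"GO:0000002"},
                     "g3": {"GO:0000001"}},
    )


@pytest.fixture(scope="session")
def small_sim():
    """Compact simulated dataset used by most pipeline-level tests."""
    cfg = SimulationConfig(
        n_groups=2, genes_per_group=20, n_informative_per_group=10,
        n_noise=40, n_samples=60, seed=11,
    )
    return cfg, generate(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """The study-condition simulation (generator defaults, seed 42)."""
    cfg = SimulationConfig()
    return cfg, generate(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
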