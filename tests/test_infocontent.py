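import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ppigcf.errors import BadLambdaError, GeneNotInGraphError
from ppigcf.infocontent import (
    DEFAULT_GOA_TABLE,
    acute_similarity_diagnostics,
    bipartition_frequencies,
    build_ic_table,
    cet,
    coverage,
    ic_threshold,
    information_content,
    select_significant,
    specificity,
)

from conftest import make_annotation_set


def deep_annos(depths, annotations):
    """Chain ontology GO:0000001 (root) <- ... with terms named by depth."""
    edges = [("GO:0000001", None)]
    terms = {0: "GO:0000001"}
    for d in range(1, max(depths) + 1):
        terms[d] = f"GO:{d + 1:07d}"
        edges.append((terms[d], terms[d - 1]))
    return terms, make_annotation_set(
        edges,
        {g: {terms[d]} for g, d in annotations.items()},
    )


class TestSpecificity:
    def test_deepest_term_scores_one(self):
        _, annos = deep_annos([7], {"g": 7})
        assert specificity("g", annos) == pytest.approx(1.0)

    def test_root_only_scores_zero(self):
        _, annos = deep_annos([3], {"g": 0})
        assert specificity("g", annos) == 0.0

    def test_log_depth_ratio(self):
        _, annos = deep_annos([7], {"g": 3})
        assert specificity("g", annos) == pytest.approx(
            math.log(4) / math.log(8)
        )

    def test_monotone_in_depth(self):
        _, annos = deep_annos([5], {f"g{d}": d for d in range(6)})
        values = [specificity(f"g{d}", annos) for d in range(6)]
        assert values == sorted(values)


class TestCoverage:
    def test_leaf_term_full_coverage(self):
        _, annos = deep_annos([4], {"g": 4})
        assert coverage("g", annos) == 1.0

    def test_all_descendants_zero_coverage(self):
        _, annos = deep_annos([4], {"g": 0})
        assert coverage("g", annos) == 0.0

    def test_descendant_fraction(self):
        # chain of 11 terms: the term at depth 8 has 2 descendants of the
        # 10 other terms
        _, annos = deep_annos([10], {"g": 8})
        assert coverage("g", annos) == pytest.approx(0.8)


class TestCet:
    @pytest.mark.parametrize(
        "spec,cov,expected", [(1, 1, 1), (0, 0.9, 0), (0.8, 0.5, 0.4)]
    )
    def test_product(self, spec, cov, expected):
        assert cet(spec, cov) == pytest.approx(expected)


class TestBipartition:
    def test_star_center(self):
        g = nx.star_graph(3)  # node 0 is the hub
        assert bipartition_frequencies(0, g) == (1.0, 0.0)

    def test_star_leaf(self):
        g = nx.star_graph(3)
        x_b, x_b_star = bipartition_frequencies(1, g)
        assert x_b == pytest.approx(1 / 3)
        assert x_b_star == pytest.approx(2 / 3)

    def test_path_endpoint(self):
        g = nx.path_graph(3)
        assert bipartition_frequencies(0, g) == (0.5, 0.5)

    def test_complement_sums_to_one(self, rng):
        g = nx.gnp_random_graph(20, 0.3, seed=3)
        for node in g.nodes:
            x_b, x_b_star = bipartition_frequencies(node, g)
            assert x_b + x_b_star == pytest.approx(1.0)

    def test_missing_gene(self):
        with pytest.raises(GeneNotInGraphError):
            bipartition_frequencies("nope", nx.path_graph(3))


class TestInformationContent:
    @pytest.mark.parametrize(
        "x_b,expected",
        [(0.5, 1.0), (1.0, 0.0), (0.0, 0.0), (0.25, 0.8112781244591328)],
    )
    def test_binary_entropy_under_default_lambda(self, x_b, expected):
        assert information_content(x_b, 1 - x_b) == pytest.approx(expected)

    def test_lambda_zero_rejected(self):
        with pytest.raises(BadLambdaError):
            information_content(0.5, 0.5, 0.0)

    def test_lambda_rescales(self):
        assert information_content(0.5, 0.5, -2.0) == pytest.approx(0.5)

    def test_concave_with_peak_at_half(self):
        grid = np.linspace(0.0, 1.0, 21)
        values = [information_content(p, 1 - p) for p in grid]
        assert max(values) == pytest.approx(1.0)
        assert values.index(max(values)) == 10
        # concavity: second differences non-positive
        second = np.diff(values, 2)
        assert (second <= 1e-12).all()


class TestAcuteDiagnostics:
    @pytest.mark.parametrize(
        "x_b,expected", [(0.5, 0.0), (1.0, -1.0), (0.9, -0.8)]
    )
    def test_conflict_derivative(self, x_b, expected):
        c_diag, _ = acute_similarity_diagnostics(x_b, 1 - x_b)
        assert c_diag == pytest.approx(expected)

    def test_acute_similarity_undefined_on_unit_interval(self):
        # p log2 p <= 0 for p in (0, 1]: the diagnostic stays undefined
        for x_b in (0.1, 0.5, 0.9):
            _, as_diag = acute_similarity_diagnostics(x_b, 1 - x_b)
            assert as_diag is None


class TestIcThreshold:
    def test_constant_table(self):
        table = pd.DataFrame(np.full((6, 4), 0.5))
        assert ic_threshold(table) == pytest.approx(0.5)

    def test_single_cell_table(self):
        assert ic_threshold(pd.DataFrame([[0.9]])) == pytest.approx(0.9)

    def test_packaged_default_mean(self):
        # exact mean 0.646650 prints as 0.6467 at 4 d.p.
        assert ic_threshold(DEFAULT_GOA_TABLE) == pytest.approx(0.64665)


class TestSelectSignificant:
    def _table(self, graph, annos):
        return build_ic_table(list(graph.nodes), graph, annos)

    def test_boundary_is_strict(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {0: "a", 1: "b", 2: "c"})
        _, annos = deep_annos([3], {"a": 3, "b": 3, "c": 3})
        table = self._table(g, annos)
        # endpoints have IC exactly 1; threshold 1 must eliminate them
        res = select_significant(table, delta=1.0)
        assert res.kept == set()
        assert set(res.eliminated.values()) == {"LOW_IC"}

    def test_all_above_threshold_kept(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {0: "a", 1: "b", 2: "c"})
        _, annos = deep_annos([3], {"a": 3, "b": 3, "c": 3})
        # scores are non-negative, so any negative threshold keeps all
        res = select_significant(self._table(g, annos), delta=-0.5)
        assert res.kept == {"a", "b", "c"}
        # the path centre is linked to its whole component (x_b = 1, IC 0)
        res0 = select_significant(self._table(g, annos), delta=0.0)
        assert res0.kept == {"a", "c"} and res0.eliminated == {"b": "LOW_IC"}

    def test_matches_exhaustive_scan(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=9)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        _, annos = deep_annos([3], {f"g{i}": 3 for i in range(15)})
        table = self._table(g, annos)
        delta = 0.6467
        res = select_significant(table, delta=delta)
        expected = {
            gene for gene in table.table.index
            if table.table.loc[gene, "score"] > delta
        }
        assert res.kept == expected

    def test_monotone_in_delta(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=10)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        _, annos = deep_annos([3], {f"g{i}": 3 for i in range(15)})
        table = self._table(g, annos)
        previous = None
        for delta in (0.0, 0.3, 0.6, 0.9, 1.0):
            kept = select_significant(table, delta=delta).kept
            if previous is not None:
                assert kept <= previous
            previous = kept
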