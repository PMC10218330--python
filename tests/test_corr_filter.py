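import numpy as np
import pandas as pd
import pytest

from ppigcf.containers import ExpressionMatrix
from ppigcf.corr_filter import (
    apply_filter,
    drop_negative_pcc,
    likelihood_score,
    nscc_matrix,
    pearson_matrix,
    resolve_theta_r,
    run_correlation_stage,
    semantic_similarity,
    surviving_pairs,
)
from ppigcf.errors import TooFewSamplesError, ZeroGrandMeanError


def em_from_rows(rows, genes=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(rows, index=genes,
                     columns=[f"s{j}" for j in range(rows.shape[1])])
    )


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_printed_toy_vectors(self, x, y, expected):
        r = pearson_matrix(em_from_rows([x, y]))
        assert r[0, 1] == pytest.approx(expected)

    def test_population_moments(self):
        # explicit population-moment evaluation: covariance sum / (n sx sy)
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 4])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = len(x) * x.std() * y.std()
        r = pearson_matrix(em_from_rows([x, y]))
        assert r[0, 1] == pytest.approx(num / den)

    def test_too_few_samples(self):
        with pytest.raises(TooFewSamplesError):
            pearson_matrix(em_from_rows([[1.0], [2.0]]))

    def test_zero_variance_gene(self):
        r = pearson_matrix(em_from_rows([[1, 2, 3], [5, 5, 5]]))
        assert r[0, 1] == 0.0 and r[1, 1] == 1.0


class TestDropNegativePcc:
    def _r(self, rows):
        r = np.array(rows, dtype=float)
        np.fill_diagonal(r, 1.0)
        return r

    def test_mean_policy_removes_negative_mean(self):
        r = self._r([[1, -0.2, -0.4], [-0.2, 1, 0.5], [-0.4, 0.5, 1]])
        kept, removed = drop_negative_pcc(r, ["a", "b", "c"], "mean")
        assert "a" in removed and removed["a"] == "NEGATIVE_PCC"

    def test_mean_policy_keeps_positive_mean(self):
        r = self._r([[1, 0.9, -0.1], [0.9, 1, 0.2], [-0.1, 0.2, 1]])
        kept, removed = drop_negative_pcc(r, ["a", "b", "c"], "mean")
        assert "a" in kept

    def test_any_policy_is_stricter(self):
        r = self._r([[1, 0.9, -0.1], [0.9, 1, 0.2], [-0.1, 0.2, 1]])
        kept, removed = drop_negative_pcc(r, ["a", "b", "c"], "any")
        assert "a" in removed and "c" in removed and kept == ["b"]

    def test_majority_policy(self):
        r = self._r([[1, -0.2, 0.4, -0.3], [-0.2, 1, 0.5, 0.1],
                     [0.4, 0.5, 1, 0.2], [-0.3, 0.1, 0.2, 1]])
        kept, removed = drop_negative_pcc(r, list("abcd"), "majority")
        assert "a" in removed  # 2 of 3 entries negative
        assert set(kept) == {"b", "c", "d"}


class TestNscc:
    def test_two_genes_single_term_normalisation(self):
        r = np.array([[1.0, 0.7], [0.7, 1.0]])
        R2 = nscc_matrix(r)
        assert R2[0, 1] == pytest.approx(1.0)
        assert R2[0, 0] == 0.0

    def test_three_gene_shares(self):
        r = np.array([[1, 0.6, 0.8], [0.6, 1, 0.0], [0.8, 0.0, 1.0]])
        R2 = nscc_matrix(r)
        assert R2[0, 1] == pytest.approx(0.36)
        assert R2[0, 2] == pytest.approx(0.64)

    def test_rows_sum_to_one(self, rng):
        r = np.corrcoef(rng.standard_normal((10, 15)))
        R2 = nscc_matrix(r)
        assert np.allclose(R2.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        r = np.corrcoef(rng.standard_normal((50, 20)))
        R2 = nscc_matrix(r)
        for i in range(50):
            denom = sum(r[i, k] ** 2 for k in range(50) if k != i)
            for j in range(50):
                expected = 0.0 if i == j else r[i, j] ** 2 / denom
                assert R2[i, j] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_row_stays_zero(self):
        r = np.eye(3)
        R2 = nscc_matrix(r)
        assert (R2 == 0).all()


class TestLikelihoodScore:
    def test_min_max_boundaries_and_midpoint(self):
        R2 = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.5], [0.8, 0.5, 0.0]])
        ll = likelihood_score(R2)
        assert ll[0, 1] == 0.0  # entry at the minimum
        assert ll[0, 2] == 1.0  # entry at the maximum
        assert ll[1, 2] == pytest.approx(0.5)  # midpoint of min and max

    def test_degenerate_range_flat_half(self):
        R2 = np.full((3, 3), 0.5)
        np.fill_diagonal(R2, 0.0)
        ll = likelihood_score(R2)
        assert (ll[~np.eye(3, dtype=bool)] == 0.5).all()


class TestSemanticSimilarity:
    def test_constant_genes_at_group_mean(self):
        em = em_from_rows([[3.0, 3.0], [3.0, 3.0]])
        sem, mu = semantic_similarity(em)
        assert mu == 3.0 and sem[0, 1] == pytest.approx(1.0)

    def test_direct_evaluation(self):
        em = em_from_rows([[1.0, 1.0], [4.0, 4.0]])
        sem, mu = semantic_similarity(em)
        assert mu == 2.5
        assert sem[0, 1] == pytest.approx(4 / 6.25)

    def test_symmetry(self, rng):
        em = em_from_rows(rng.uniform(1, 10, (5, 8)))
        sem, _ = semantic_similarity(em)
        assert np.allclose(sem, sem.T)

    def test_zero_grand_mean_needs_offset(self):
        em = em_from_rows([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ZeroGrandMeanError):
            semantic_similarity(em)
        sem, mu = semantic_similarity(em, offset=5.0)
        assert mu == 5.0


class TestApplyFilter:
    def test_good_pair_survives(self):
        r = np.array([[1, 0.9], [0.9, 1]])
        R2 = np.array([[0, 0.01], [0.01, 0]])
        ll = np.array([[0, 0.9], [0.9, 0]])
        sem = np.array([[1, 0.9], [0.9, 1]])
        res, surv = apply_filter(r, R2, ll, sem, ["a", "b"], "auto")
        assert res.kept == {"a", "b"} and surv[0, 1]

    def test_negative_correlation_never_survives(self):
        r = np.array([[1, -0.9], [-0.9, 1]])
        perfect = np.array([[0, 1.0], [1.0, 0]])
        res, surv = apply_filter(
            r, 1 - perfect, perfect, perfect, ["a", "b"], 1.0, 0.0, 0.0
        )
        assert res.kept == set()
        assert res.eliminated == {"a": "WEAK_CORRELATION",
                                  "b": "WEAK_CORRELATION"}

    def test_matches_exhaustive_pair_scan(self, rng):
        k = 10
        X = rng.standard_normal((k, 30)) + 5.0
        em = em_from_rows(X)
        r = pearson_matrix(em)
        R2 = nscc_matrix(r)
        ll = likelihood_score(R2)
        sem, _ = semantic_similarity(em)
        theta_R = resolve_theta_r("auto", k)
        surv = surviving_pairs(r, R2, ll, sem, theta_R, 0.5, 0.5)
        for i in range(k):
            for j in range(k):
                if i == j:
                    assert not surv[i, j]
                    continue
                ij = (r[i, j] > 0 and R2[i, j] <= theta_R
                      and ll[i, j] >= 0.5 and sem[i, j] >= 0.5)
                ji = (r[j, i] > 0 and R2[j, i] <= theta_R
                      and ll[j, i] >= 0.5 and sem[j, i] >= 0.5)
                assert surv[i, j] == (ij or ji)

    def test_tightening_thresholds_never_grows_rd2(self, rng):
        k = 12
        em = em_from_rows(rng.standard_normal((k, 25)) + 5.0)
        r = pearson_matrix(em)
        R2 = nscc_matrix(r)
        ll = likelihood_score(R2)
        sem, _ = semantic_similarity(em)
        genes = em.genes
        base, _ = apply_filter(r, R2, ll, sem, genes, 0.2, 0.3, 0.3)
        for tR, tL, tS in [(0.1, 0.3, 0.3), (0.2, 0.6, 0.3),
                           (0.2, 0.3, 0.6), (0.05, 0.8, 0.8)]:
            tighter, _ = apply_filter(r, R2, ll, sem, genes, tR, tL, tS)
            assert tighter.kept <= base.kept


class TestRunCorrelationStage:
    def test_rd2_subset_of_input_and_reasons_partition(self, rng):
        em = em_from_rows(rng.standard_normal((8, 20)) + 5.0)
        res, tables, surv = run_correlation_stage(em)
        assert res.kept <= set(em.genes)
        assert res.kept | set(res.eliminated) == set(em.genes)

    def test_negative_pcc_genes_never_in_rd2(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(30)
        rows = [base + 0.1 * rng.standard_normal(30) for _ in range(4)]
        rows.append(-base + 0.1 * rng.standard_normal(30))  # anti-correlated
        em = em_from_rows(np.array(rows) + 10.0)
        res, _, _ = run_correlation_stage(em)
        assert res.eliminated.get("g4") == "NEGATIVE_PCC"
        assert "g4" not in res.kept

    def test_single_gene_cannot_pair(self):
        em = em_from_rows([[1.0, 2.0, 3.0]])
        res, tables, surv = run_correlation_stage(em)
        assert res.kept == set()
        assert res.eliminated == {"g0": "WEAK_CORRELATION"}
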