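"""Correlation filter: Pearson, NSCC, likelihood and semantic similarity.

Third pipeline layer, run per group on the RD1 survivors. Genes whose
off-diagonal correlations are negative on average are dropped first; on the
survivors the normalised squared correlation coefficient (NSCC — each
squared correlation divided by its row sum, diagonal excluded), a min-max
likelihood score over the NSCC entries, and an expression-product semantic
similarity are computed. A gene pair survives when the correlation is
positive, its NSCC share is at most theta_R (a small share marks strong,
non-redundant correlation), its likelihood score is at least theta_L, and
its semantic similarity is at least theta_S. RD2 keeps every gene belonging
to at least one surviving pair.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CorrelationTables, ExpressionMatrix, StageResult
from .errors import TooFewSamplesError, ZeroGrandMeanError

log = logging.getLogger(__name__)

NEGATIVE_PCC_POLICIES = ("mean", "any", "majority")
DEFAULT_THETA_L = 0.5
DEFAULT_THETA_S = 0.5


def pearson_matrix(expr: ExpressionMatrix) -> np.ndarray:
    """Population-moment Pearson correlation matrix (genes x genes).

    Zero-variance genes get zero off-diagonal correlations (unit diagonal)
    with a logged warning.
    """
    if expr.n_samples < 2:
        raise TooFewSamplesError(
            f"need >= 2 samples, got {expr.n_samples}"
        )
    X = expr.values.to_numpy(dtype=float)
    sd = X.std(axis=1)  # population SD across samples
    flat = np.where(sd == 0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(X)
    r = np.atleast_2d(r)
    if flat.size:
        log.warning("%d zero-variance gene(s); correlations set to 0",
                    flat.size)
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def drop_negative_pcc(
    r: np.ndarray, genes: list[str], policy: str = "mean"
) -> tuple[list[str], dict[str, str]]:
    """Remove genes with negative correlation per the chosen policy.

    mean (default): off-diagonal mean < 0; any: at least one negative entry;
    majority: more than half the entries negative.
    """
    if policy not in NEGATIVE_PCC_POLICIES:
        raise ValueError(f"unknown negative-PCC policy {policy!r}")
    k = len(genes)
    if k == 1:
        return list(genes), {}
    off = r.copy()
    np.fill_diagonal(off, np.nan)
    removed: dict[str, str] = {}
    survivors: list[str] = []
    for i, g in enumerate(genes):
        row = off[i][~np.isnan(off[i])]
        if policy == "mean":
            bad = row.mean() < 0
        elif policy == "any":
            bad = bool((row < 0).any())
        else:
            bad = (row < 0).sum() > row.size / 2
        if bad:
            removed[g] = "NEGATIVE_PCC"
        else:
            survivors.append(g)
    return survivors, removed


def nscc_matrix(r: np.ndarray) -> np.ndarray:
    """Row-normalised squared correlations, diagonal excluded and zeroed.

    Rows whose off-diagonal correlations are all zero stay all-zero (the
    gene is uncorrelated with everything; flagged by the caller).
    """
    r2 = r.astype(float) ** 2
    np.fill_diagonal(r2, 0.0)
    sums = r2.sum(axis=1, keepdims=True)
    zero_rows = np.where(sums[:, 0] == 0)[0]
    if zero_rows.size:
        log.warning("%d all-zero NSCC row(s)", zero_rows.size)
        sums[zero_rows] = 1.0  # leaves those rows at exactly 0
    return r2 / sums


def likelihood_score(R2: np.ndarray) -> np.ndarray:
    """Min-max normalisation of the off-diagonal NSCC entries to [0, 1].

    Degenerate groups (fewer than two distinct off-diagonal values) get a
    flat 0.5, logged.
    """
    k = R2.shape[0]
    mask = ~np.eye(k, dtype=bool)
    off = R2[mask]
    if off.size == 0 or np.unique(off).size < 2:
        log.warning("degenerate NSCC range; likelihood score set to 0.5")
        ll = np.full_like(R2, 0.5)
        np.fill_diagonal(ll, 0.0)
        return ll
    lo, hi = off.min(), off.max()
    ll = (R2 - lo) / (hi - lo)
    np.fill_diagonal(ll, 0.0)
    return ll


def semantic_similarity(
    expr: ExpressionMatrix, offset: float | None = None
) -> tuple[np.ndarray, float]:
    """sem[i][j] = mean_s(x_i[s] * x_j[s]) / mu_g^2, mu_g the grand mean.

    A zero grand mean is an error unless a shift ``offset`` is configured.
    Returns (sem, mu_g actually used).
    """
    X = expr.values.to_numpy(dtype=float)
    mu = X.mean()
    if mu == 0.0:
        if offset is None:
            raise ZeroGrandMeanError(
                "grand mean is 0; configure sem_offset to shift expression"
            )
        log.info("grand mean 0; shifting expression by %g", offset)
        X = X + offset
        mu = X.mean()
        if mu == 0.0:
            raise ZeroGrandMeanError("grand mean still 0 after offset")
    sem = (X @ X.T) / X.shape[1] / mu**2
    return sem, mu


def resolve_theta_r(theta_R, k: int) -> float:
    """'auto' -> 1/(k-1), the uniform NSCC row share for a k-gene group."""
    if theta_R == "auto" or theta_R is None:
        return 1.0 / (k - 1) if k > 1 else 1.0
    return float(theta_R)


def surviving_pairs(
    r: np.ndarray,
    R2: np.ndarray,
    ll: np.ndarray,
    sem: np.ndarray,
    theta_R: float,
    theta_L: float,
    theta_S: float,
) -> np.ndarray:
    """Boolean matrix of surviving ordered pairs (diagonal False).

    Pair (i, j) survives iff r > 0, R2 <= theta_R, ll >= theta_L and
    sem >= theta_S. The returned matrix is symmetrised (a pair counts when
    it survives in either orientation).
    """
    surv = (r > 0) & (R2 <= theta_R) & (ll >= theta_L) & (sem >= theta_S)
    np.fill_diagonal(surv, False)
    return surv | surv.T


def apply_filter(
    r: np.ndarray,
    R2: np.ndarray,
    ll: np.ndarray,
    sem: np.ndarray,
    genes: list[str],
    theta_R,
    theta_L: float = DEFAULT_THETA_L,
    theta_S: float = DEFAULT_THETA_S,
) -> tuple[StageResult, np.ndarray]:
    """RD2 selection: keep genes with at least one surviving pair.

    Returns the stage result plus the symmetric surviving-pair matrix (the
    graph the information-content stage scores over).
    """
    theta_R = resolve_theta_r(theta_R, len(genes))
    surv = surviving_pairs(r, R2, ll, sem, theta_R, theta_L, theta_S)
    has_pair = surv.any(axis=1)
    kept = {g for g, ok in zip(genes, has_pair) if ok}
    eliminated = {
        g: "WEAK_CORRELATION" for g, ok in zip(genes, has_pair) if not ok
    }
    scores = pd.DataFrame(
        {"n_surviving_pairs": surv.sum(axis=1).astype(float)}, index=genes
    ).sort_index()
    result = StageResult(stage="RD2", kept=kept, eliminated=eliminated,
                         scores=scores)
    return result, surv


def run_correlation_stage(
    expr: ExpressionMatrix,
    policy: str = "mean",
    theta_R="auto",
    theta_L: float = DEFAULT_THETA_L,
    theta_S: float = DEFAULT_THETA_S,
    sem_offset: float | None = None,
) -> tuple[StageResult, CorrelationTables | None, np.ndarray | None]:
    """Full stage on one group's RD1 survivors: negative-PCC drop, then the
    NSCC/likelihood/semantic gates on the (renormalised) survivor matrices.

    Returns (RD2 result over the stage's input genes, tables on the
    negative-PCC survivors, surviving-pair matrix aligned to those genes).
    """
    genes = list(expr.genes)
    if len(genes) < 2:
        return (
            StageResult(
                stage="RD2", kept=set(),
                eliminated={g: "WEAK_CORRELATION" for g in genes},
            ),
            None,
            None,
        )
    r0 = pearson_matrix(expr)
    survivors, removed = drop_negative_pcc(r0, genes, policy)
    if len(survivors) < 2:
        eliminated = dict(removed)
        eliminated.update(
            {g: "WEAK_CORRELATION" for g in survivors}
        )
        return (
            StageResult(stage="RD2", kept=set(), eliminated=eliminated),
            None,
            None,
        )
    sub = expr.subset(survivors)
    r = pearson_matrix(sub)  # recomputed on survivors -> rows renormalise
    R2 = nscc_matrix(r)
    ll = likelihood_score(R2)
    sem, mu = semantic_similarity(sub, offset=sem_offset)
    result, surv = apply_filter(
        r, R2, ll, sem, survivors, theta_R, theta_L, theta_S
    )
    eliminated = dict(removed)
    eliminated.update(result.eliminated)
    full = StageResult(stage="RD2", kept=result.kept, eliminated=eliminated,
                       scores=result.scores)
    tables = CorrelationTables(
        genes=survivors, r=r, R2=R2, ll=ll, sem=sem, mu_g=mu
    )
    return full, tables, surv
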