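"""All-pairs co-expression scoring: discretized mutual information and
Spearman correlation, pooled permutation p-values, and ranked edge lists.

Mutual information is the plug-in estimate in bits on an equal-frequency
discretization with ``B = max(2, round(sqrt(n)))`` bins per gene, the
standard histogram estimator in the ARACNe family of network-inference
tools.  Spearman is rank correlation with average ranks on ties.  Both
run over all gene pairs in gene-blocks so memory stays bounded; results
are identical for any block size.

Significance uses a pooled permutation null: random gene pairs are scored
after independently permuting one profile, and each edge's p-value is the
add-one upper-tail proportion against the pooled null.  A per-edge
permutation null at p < 1e-5 resolution is infeasible at all-pairs scale;
pooling is the standard compromise and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, RankedEdgeList

__all__ = [
    "NullDistribution",
    "discretize_equal_frequency",
    "default_bins",
    "mutual_information_matrix",
    "spearman_matrix",
    "permutation_null",
    "p_values_from_null",
    "rank_edges",
    "constant_genes",
]


@dataclass
class NullDistribution:
    method: str
    n_permutations: int
    null_scores: np.ndarray
    seed: int
    pairs_per_permutation: int = 0

    def p_value(self, score: float | np.ndarray) -> np.ndarray:
        return p_values_from_null(np.asarray(score, dtype=float), self)


def default_bins(n_samples: int) -> int:
    return max(2, int(round(np.sqrt(n_samples))))


def constant_genes(matrix: ExpressionMatrix) -> list[str]:
    """Genes with zero range across samples (undiscretizable; their pairs
    are scored 0 and flagged)."""
    arr = matrix.data.to_numpy(dtype=float)
    flat = np.ptp(arr, axis=1) == 0
    return [g for g, f in zip(matrix.gene_ids, flat) if f]


def discretize_equal_frequency(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value to one of ``n_bins`` equal-frequency bins.

    Values are ordered (stable sort, so ties keep input order) and the
    ordered positions split into bins of near-equal occupancy; when
    ``n_bins`` divides ``n`` the occupancy is exactly equal, making
    MI(X, X) exactly log2(B).
    """
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    bins = np.empty(n, dtype=np.int64)
    bins[order] = (np.arange(n) * n_bins) // n
    return bins


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    """Plug-in MI in bits for one discretized pair."""
    n = len(bx)
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).reshape(
        n_bins, n_bins
    )
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    p = joint[nz] / n
    return float(np.sum(p * np.log2(joint[nz] * n / np.outer(px, py)[nz])))


def mutual_information_matrix(
    matrix: ExpressionMatrix,
    n_bins: int | None = None,
    block_size: int | None = None,
) -> pd.DataFrame:
    """All-pairs plug-in mutual information in bits.

    Symmetric with a zero diagonal (self-pairs excluded downstream).
    Constant genes contribute 0 to every pair.  ``block_size`` caps the
    number of genes held in the per-bin indicator matrices at once; the
    result is exactly block-size invariant because each joint count is a
    plain integer dot product.
    """
    n = matrix.shape[1]
    if n < 8:
        raise ValueError(f"mutual information needs >= 8 samples, got {n}")
    b = n_bins if n_bins is not None else default_bins(n)
    arr = matrix.data.to_numpy(dtype=float)
    g = arr.shape[0]
    bins = np.vstack([discretize_equal_frequency(row, b) for row in arr])
    const = np.ptp(arr, axis=1) == 0

    # one-hot indicators per bin, genes x samples, float32 for BLAS
    marg = np.stack([(bins == k).sum(axis=1) for k in range(b)], axis=1)  # g x b
    mi = np.zeros((g, g), dtype=np.float64)
    bs = block_size if block_size is not None else g
    starts = range(0, g, bs)
    for i0 in starts:
        i1 = min(i0 + bs, g)
        ind_i = [(bins[i0:i1] == k).astype(np.float32) for k in range(b)]
        for j0 in range(0, g, bs):
            j1 = min(j0 + bs, g)
            ind_j = (
                ind_i
                if (j0, j1) == (i0, i1)
                else [(bins[j0:j1] == k).astype(np.float32) for k in range(b)]
            )
            block = np.zeros((i1 - i0, j1 - j0), dtype=np.float64)
            for kx in range(b):
                mx = marg[i0:i1, kx].astype(np.float64)
                for ky in range(b):
                    c = np.rint(ind_i[kx] @ ind_j[ky].T).astype(np.float64)
                    my = marg[j0:j1, ky].astype(np.float64)
                    denom = np.outer(mx, my)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        term = (c / n) * np.log2(c * n / denom)
                    block += np.where(c > 0, term, 0.0)
            mi[i0:i1, j0:j1] = block
    mi = 0.5 * (mi + mi.T)  # exact symmetry despite float accumulation order
    mi[np.abs(mi) < 1e-12] = 0.0
    np.clip(mi, 0.0, None, out=mi)
    mi[const, :] = 0.0
    mi[:, const] = 0.0
    np.fill_diagonal(mi, 0.0)
    return pd.DataFrame(mi, index=matrix.gene_ids, columns=matrix.gene_ids)


def spearman_matrix(
    matrix: ExpressionMatrix, block_size: int | None = None
) -> pd.DataFrame:
    """All-pairs Spearman rank correlation (average ranks on ties).

    Constant genes get 0 against every partner.
    """
    if matrix.shape[1] < 4:
        raise ValueError(f"Spearman needs >= 4 samples, got {matrix.shape[1]}")
    arr = matrix.data.to_numpy(dtype=float)
    const = np.ptp(arr, axis=1) == 0
    ranks = stats.rankdata(arr, axis=1).astype(np.float64)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    norm[norm == 0] = 1.0
    ranks /= norm[:, None]
    g = ranks.shape[0]
    bs = block_size if block_size is not None else g
    rho = np.empty((g, g), dtype=np.float64)
    for i0 in range(0, g, bs):
        i1 = min(i0 + bs, g)
        rho[i0:i1] = ranks[i0:i1] @ ranks.T
    np.clip(rho, -1.0, 1.0, out=rho)
    rho = 0.5 * (rho + rho.T)
    rho[const, :] = 0.0
    rho[:, const] = 0.0
    np.fill_diagonal(rho, 0.0)
    return pd.DataFrame(rho, index=matrix.gene_ids, columns=matrix.gene_ids)


def _score_pair(x: np.ndarray, y: np.ndarray, method: str, n_bins: int) -> float:
    if method == "mi":
        bx = discretize_equal_frequency(x, n_bins)
        by = discretize_equal_frequency(y, n_bins)
        return _mi_from_bins(bx, by, n_bins)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def permutation_null(
    matrix: ExpressionMatrix,
    method: str,
    n_permutations: int = 20,
    pairs_per_permutation: int = 1000,
    seed: int = 0,
    n_bins: int | None = None,
) -> NullDistribution:
    """Pooled permutation null for co-expression scores.

    Each permutation draws ``pairs_per_permutation`` random gene pairs and
    scores them after independently permuting one profile, destroying any
    dependence while keeping both marginals.  The pooled null supports
    p-values down to ``1 / (1 + n_permutations * pairs_per_permutation)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    arr = matrix.data.to_numpy(dtype=float)
    g, n = arr.shape
    b = n_bins if n_bins is not None else default_bins(n)
    scores = np.empty(n_permutations * pairs_per_permutation, dtype=np.float64)
    k = 0
    for _ in range(n_permutations):
        ii = rng.integers(0, g, size=pairs_per_permutation)
        jj = rng.integers(0, g, size=pairs_per_permutation)
        for i, j in zip(ii, jj):
            y = rng.permutation(arr[j])
            scores[k] = abs(_score_pair(arr[i], y, method, b))
            k += 1
    return NullDistribution(method, n_permutations, scores, seed, pairs_per_permutation)


def p_values_from_null(abs_scores: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Add-one upper-tail p-value against the pooled null:
    ``p = (1 + #{null >= s}) / (1 + N)``."""
    pool = np.sort(null.null_scores)
    n_null = len(pool)
    s = np.atleast_1d(np.asarray(abs_scores, dtype=float))
    n_ge = n_null - np.searchsorted(pool, s, side="left")
    return (1.0 + n_ge) / (1.0 + n_null)


def rank_edges(
    scores: pd.DataFrame,
    null: NullDistribution | None = None,
    top_k: int | None = None,
    method: str = "unknown",
    n_samples: int | None = None,
    estimator_params: dict | None = None,
) -> RankedEdgeList:
    """Rank all pairs by descending absolute score into a canonical edge
    list; ties break by (gene_a, gene_b) lexicographic order.

    ``null`` attaches pooled-permutation p-values; ``top_k`` truncates
    after ranking (requesting more pairs than exist returns all).
    """
    order = sorted(scores.index)  # canonical rows need gene_a < gene_b
    scores = scores.loc[order, order]
    genes = np.asarray(scores.index, dtype=object)
    arr = scores.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("score table must be symmetric")
    iu, ju = np.triu_indices(len(genes), k=1)
    s = arr[iu, ju]
    a = genes[iu]
    b = genes[ju]
    df = pd.DataFrame({"gene_a": a, "gene_b": b, "score": s, "abs_score": np.abs(s)})
    df.sort_values(
        ["abs_score", "gene_a", "gene_b"],
        ascending=[False, True, True],
        inplace=True,
        kind="mergesort",
    )
    if top_k is not None:
        top_k = int(top_k)
        if top_k < len(df):
            df = df.iloc[:top_k]
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["p_value"] = (
        p_values_from_null(df["abs_score"].to_numpy(), null)
        if null is not None
        else np.nan
    )
    df = df[["gene_a", "gene_b", "score", "abs_score", "rank", "p_value"]]
    return RankedEdgeList(
        df,
        method=method,
        n_samples=n_samples,
        estimator_params=estimator_params or {},
    )
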