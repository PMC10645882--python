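"""Gene filtering and normalization for joint cancer+control count matrices.

The stage order is GC-content correction, gene-length correction (both
within-sample full-quantile over equal-frequency bins), between-lane
full-quantile normalization across samples, then TMM scaling.  Low-count
genes are removed first by three rules evaluated on the joint matrix: mean
at or below the 0.25 quantile of gene means, zero in a majority of
samples, or mean below 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = [
    "NormalizationReport",
    "filter_low_expression",
    "tmm_size_factors",
    "gc_length_correct",
    "between_lane_quantile",
    "normalize",
    "pca_separation_table",
]


@dataclass
class NormalizationReport:
    genes_removed_by_rule: dict[str, int] = field(default_factory=dict)
    removed_genes: dict[str, list[str]] = field(default_factory=dict)
    size_factors: pd.Series | None = None
    steps_applied: list[str] = field(default_factory=list)
    quantile_value: float | None = None


def filter_low_expression(
    matrix: ExpressionMatrix,
    quantile_cut: float = 0.25,
    zero_majority_fraction: float = 0.5,
    mean_cut: float = 10.0,
    quantile_value: float | None = None,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Remove low-count genes; a gene is dropped if it hits ANY rule.

    Rules, each evaluated on the joint raw matrix:

    * mean expression at or below the ``quantile_cut`` quantile of gene
      means (linear-interpolation / type-7 quantile);
    * zeros in strictly more than ``zero_majority_fraction`` of samples;
    * mean expression strictly below ``mean_cut``.

    The report itemizes removals per rule and echoes the realized quantile
    threshold; pass that back as ``quantile_value`` to re-apply the filter
    idempotently (a re-computed quantile on already-filtered genes would
    keep eating into the survivors).
    """
    data = matrix.data
    means = data.mean(axis=1)
    if quantile_value is not None:
        q = float(quantile_value)
    else:
        q = float(np.quantile(means.to_numpy(), quantile_cut))  # type-7 default
    zero_frac = (data == 0).mean(axis=1)

    rule_masks = {
        "quantile": means <= q,
        "zero_majority": zero_frac > zero_majority_fraction,
        "low_mean": means < mean_cut,
    }
    report = NormalizationReport(
        genes_removed_by_rule={r: int(m.sum()) for r, m in rule_masks.items()},
        removed_genes={r: data.index[m].tolist() for r, m in rule_masks.items()},
        steps_applied=["filter_low_expression"],
        quantile_value=q,
    )
    drop = rule_masks["quantile"] | rule_masks["zero_majority"] | rule_masks["low_mean"]
    kept = data.loc[~drop]
    if kept.empty:
        raise ValueError("all genes removed by low-expression filters")
    return ExpressionMatrix(kept, matrix.phenotype), report


def _choose_reference(data: pd.DataFrame) -> str:
    """Sample whose upper-quartile of library-scaled counts is closest to
    the mean upper-quartile (the usual TMM reference rule)."""
    scaled = data / data.sum(axis=0)
    uq = scaled.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_size_factors(
    matrix: ExpressionMatrix,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    For each sample vs the reference: M = log2 ratio of library-scaled
    counts, A = average log2 abundance, computed over genes positive in
    both.  The top/bottom ``trim_m`` of M and ``trim_a`` of A are trimmed,
    the rest averaged with inverse-variance (binomial delta-method)
    weights.  The returned factor is the full per-sample scaling —
    library size times the TMM compositional factor — normalized to
    geometric mean 1, so dividing counts by it makes samples comparable.
    """
    data = matrix.data
    if data.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = data.sum(axis=0)
    if (lib == 0).any():
        dead = lib.index[lib == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {dead}")
    ref = reference_sample if reference_sample is not None else _choose_reference(data)
    ref_counts = data[ref].to_numpy(dtype=float)
    ref_lib = float(lib[ref])

    log_factors = {}
    for s in data.columns:
        if s == ref:
            log_factors[s] = 0.0
            continue
        obs = data[s].to_numpy(dtype=float)
        ok = (obs > 0) & (ref_counts > 0)
        o, r = obs[ok], ref_counts[ok]
        ol, rl = float(lib[s]), ref_lib
        m = np.log2((o / ol) / (r / rl))
        a = 0.5 * np.log2((o / ol) * (r / rl))
        w = 1.0 / ((ol - o) / (ol * o) + (rl - r) / (rl * r))

        n = len(m)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        log_factors[s] = float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    tmm = pd.Series({s: 2.0 ** lf for s, lf in log_factors.items()}).reindex(data.columns)
    f = tmm * lib
    return f / np.exp(np.log(f).mean())  # geometric mean 1


def _quantile_bins(values: pd.Series, n_bins: int) -> pd.Series:
    """Equal-frequency binning; collapses to fewer bins on heavy ties."""
    ranks = values.rank(method="first")
    return pd.cut(ranks, bins=n_bins, labels=False)


def _within_sample_quantile_by_bin(
    data: pd.DataFrame, bins: pd.Series, n_bins: int
) -> pd.DataFrame:
    """Full-quantile normalization across bins, independently per sample.

    The reference distribution per sample is the average of per-bin
    quantile functions on a common grid; each value is replaced by the
    reference quantile at its within-bin rank, so within-bin rank order is
    preserved exactly.
    """
    out = data.copy().astype(float)
    bin_ids = bins.dropna().unique()
    for s in data.columns:
        col = data[s]
        # per-bin empirical quantile functions (sorted values on mid-rank grid)
        sorted_vals = {}
        u_grids = {}
        for b in bin_ids:
            vals = np.sort(col[bins == b].to_numpy(dtype=float))
            if len(vals) == 0:
                continue
            sorted_vals[b] = vals
            u_grids[b] = (np.arange(len(vals)) + 0.5) / len(vals)
        for b in bin_ids:
            mask = (bins == b).to_numpy()
            vals = col.to_numpy(dtype=float)[mask]
            order = np.argsort(vals, kind="mergesort")
            u = (np.arange(len(vals)) + 0.5) / len(vals)
            # reference quantile at each target rank: mean over all bins'
            # quantile functions, evaluated exactly (no intermediate grid)
            ref = np.mean(
                [np.interp(u, u_grids[b2], sorted_vals[b2]) for b2 in sorted_vals],
                axis=0,
            )
            new = np.empty_like(vals)
            new[order] = ref
            out.loc[mask, s] = new
    return out


def gc_length_correct(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    n_bins: int = 10,
    min_bin_size: int = 200,
) -> ExpressionMatrix:
    """Within-sample correction for GC-content then gene-length bias.

    Genes are binned by equal frequency on GC percent, values
    full-quantile normalized across bins within each sample, then the same
    across length bins.  Preserves within-bin rank order per sample.

    With few genes per bin, within-bin rank competition couples unrelated
    genes and fabricates co-expression; the bin count is therefore capped
    so every bin holds at least ``min_bin_size`` genes, and the step
    degrades to the identity when even 2 such bins cannot be formed.
    """
    missing = [g for g in matrix.gene_ids if g not in annotation.index]
    if missing:
        raise ValueError(f"genes missing GC/length annotation: {missing[:10]}")
    ann = annotation.loc[matrix.gene_ids]
    data = matrix.data
    for covariate in ("gc_percent", "length"):
        vals = ann[covariate]
        n_eff = min(n_bins, vals.nunique(), max(1, len(vals) // min_bin_size))
        if n_eff <= 1:
            continue  # single bin: quantile map is the identity on ranks
        bins = _quantile_bins(vals, n_eff)
        bins.index = data.index
        data = _within_sample_quantile_by_bin(data, bins, n_eff)
    return ExpressionMatrix(data, matrix.phenotype)


def between_lane_quantile(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Full-quantile normalization across samples: every sample's value
    distribution becomes the mean of the sorted columns."""
    data = matrix.data
    if data.empty:
        raise ValueError("empty matrix")
    arr = data.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="mergesort")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = ref
    return ExpressionMatrix(
        pd.DataFrame(out, index=data.index, columns=data.columns), matrix.phenotype
    )


def normalize(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    quantile_cut: float = 0.25,
    zero_majority_fraction: float = 0.5,
    mean_cut: float = 10.0,
    n_bins: int = 10,
    min_bin_size: int = 200,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Filter then run the composed normalization: GC -> length ->
    between-lane quantile -> TMM."""
    filtered, report = filter_low_expression(
        matrix, quantile_cut, zero_majority_fraction, mean_cut
    )
    corrected = gc_length_correct(
        filtered, annotation, n_bins=n_bins, min_bin_size=min_bin_size
    )
    lane = between_lane_quantile(corrected)
    factors = tmm_size_factors(lane)
    scaled = ExpressionMatrix(lane.data / factors, lane.phenotype)
    report.size_factors = factors
    report.steps_applied += ["gc_length_correct", "between_lane_quantile", "tmm"]
    return scaled, report


def pca_separation_table(matrix: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """Diagnostic replacing multivariate noise reduction: leading principal
    components per sample with phenotype labels, so phenotype separation
    can be checked from the table."""
    x = np.log1p(matrix.data.to_numpy(dtype=float)).T
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    scores = x @ vt[:n_components].T
    tab = pd.DataFrame(
        scores,
        index=matrix.sample_ids,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    if matrix.phenotype is not None:
        tab["phenotype"] = matrix.phenotype.reindex(tab.index)
    return tab
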