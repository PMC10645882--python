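"""Differential expression, gene-set over-representation, and the
community-level differential-expression trend.

The DE stage is a deliberately simplified negative-binomial Wald test in
the DESeq family: median-of-ratios size factors on the joint matrix,
per-gene NB2 dispersion by method of moments, log2 fold change from
normalized group means with a 0.5 pseudo-mean floor, a Wald z against
the normal, and Benjamini-Hochberg adjustment.  Dispersion shrinkage
toward a trend, Cook's outlier filtering and independent filtering are
intentionally absent: downstream consumers only use the sign and a
significance threshold.

Over-representation is the one-sided hypergeometric (Fisher upper tail)
of the overlap between a community and a gene set within a fixed
universe, BH-adjusted across all (community, set) pairs; a community is
"enriched" for a set below an adjusted-p threshold (default 1e-10).

The trend statistic of a gene collection is
``(n_over - n_under) / n_total`` in [-1, 1], where genes classify as
over/under when significantly differentially expressed (padj < alpha)
with the corresponding sign, and count as unclassified otherwise
(unclassified genes stay in the denominator).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "median_of_ratios_size_factors",
    "nb_wald_de",
    "classify_de",
    "bh_adjust",
    "hypergeom_enrich",
    "de_trend",
    "shared_bp_matrix",
]

DISPERSION_FLOOR = 1e-8


def median_of_ratios_size_factors(data: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median of count ratios to the
    per-gene geometric mean, over genes expressed in every sample."""
    arr = data.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(arr).mean(axis=1)
    use = np.isfinite(loggeo)
    if not use.any():
        raise ValueError("no gene is expressed in every sample; cannot form size factors")
    ratios = np.log(arr[use]) - loggeo[use, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=data.columns)


def _group_moments(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return y.mean(axis=1), y.var(axis=1, ddof=1)


def nb_wald_de(
    cancer: ExpressionMatrix,
    control: ExpressionMatrix,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """NB Wald differential expression of cancer vs control counts.

    Both matrices must share the gene universe and have at least 3
    samples each.  Genes with zero counts in every sample of both groups
    are excluded (listed in the ``excluded`` attribute of the result).
    Returns a table with base means, log2FoldChange, lfcSE, Wald stat,
    p_value, padj and the over/under/unclassified class at ``alpha``.
    """
    if list(cancer.gene_ids) != list(control.gene_ids):
        raise ValueError("cancer and control matrices must share the gene universe")
    n1, n2 = cancer.shape[1], control.shape[1]
    if n1 < 3 or n2 < 3:
        raise ValueError("need >= 3 samples per group")

    joint = pd.concat([cancer.data, control.data], axis=1)
    sf = median_of_ratios_size_factors(joint)
    norm = joint / sf
    yc = norm.iloc[:, :n1].to_numpy(dtype=float)
    yn = norm.iloc[:, n1:].to_numpy(dtype=float)

    all_zero = (joint.to_numpy() == 0).all(axis=1)
    mc, vc = _group_moments(yc)
    mn, vn = _group_moments(yn)

    # pooled NB2 method-of-moments dispersion: alpha_g = (var - mu) / mu^2
    # combined across groups with df weights, floored
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (vc - mc) / mc**2
        a2 = (vn - mn) / mn**2
    a1 = np.where(np.isfinite(a1), a1, 0.0)
    a2 = np.where(np.isfinite(a2), a2, 0.0)
    disp = ((n1 - 1) * a1 + (n2 - 1) * a2) / (n1 + n2 - 2)
    disp = np.maximum(disp, DISPERSION_FLOOR)

    pseudo = 0.5  # pseudo-mean floor stabilizes the log ratio at low counts
    lfc = np.log2(mc + pseudo) - np.log2(mn + pseudo)
    ln2 = np.log(2.0)
    var_mc = (mc + disp * mc**2) / n1
    var_mn = (mn + disp * mn**2) / n2
    se = np.sqrt(
        var_mc / ((mc + pseudo) ** 2 * ln2**2) + var_mn / ((mn + pseudo) ** 2 * ln2**2)
    )
    se = np.maximum(se, 1e-12)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {
            "gene_id": joint.index,
            "baseMean": norm.mean(axis=1).to_numpy(),
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": z,
            "p_value": p,
        }
    ).set_index("gene_id", drop=False)
    excluded = table.index[all_zero].tolist()
    table = table.loc[~all_zero]
    table["padj"] = bh_adjust(table["p_value"].to_numpy())
    table["class"] = classify_de(table, alpha=alpha)
    table.attrs["excluded"] = excluded
    table.attrs["size_factors"] = sf
    return table


def classify_de(de_table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """over / under / unclassified per gene: significant at ``alpha`` with
    positive / negative log2FC, otherwise unclassified."""
    sig = de_table["padj"] < alpha
    cls = np.where(
        sig & (de_table["log2FoldChange"] > 0),
        "over",
        np.where(sig & (de_table["log2FoldChange"] < 0), "under", "unclassified"),
    )
    return pd.Series(cls, index=de_table.index)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    communities: pd.DataFrame | Mapping[str, Iterable[str]],
    sets: GeneSetCollection,
    universe: Iterable[str],
    padj_threshold: float = 1e-10,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each community in
    each gene set.

    ``communities`` is either the flat community table (with
    ``community_id`` and ``;``-joined ``members`` columns) or a mapping
    id -> members.  Gene sets are intersected with the universe; the
    upper-tail p-value of the observed overlap is BH-adjusted across all
    (community, set) pairs and flagged enriched below ``padj_threshold``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if isinstance(communities, pd.DataFrame):
        comm = {
            row.community_id: set(row.members.split(";"))
            for row in communities.itertuples(index=False)
        }
    else:
        comm = {k: set(v) for k, v in communities.items()}
    for cid, members in comm.items():
        extra = members - uni
        if extra:
            raise ValueError(
                f"community {cid} has members outside the universe: {sorted(extra)[:5]}"
            )
    rows = []
    m_total = len(uni)
    for s in sets:
        set_members = set(s.members) & uni
        if not set_members:
            continue
        for cid, members in comm.items():
            k = len(members & set_members)
            # P(overlap >= k) drawing |community| from universe with
            # |set| successes
            p = float(
                stats.hypergeom.sf(k - 1, m_total, len(set_members), len(members))
            )
            rows.append(
                {
                    "community_id": cid,
                    "set_id": s.set_id,
                    "community_size": len(members),
                    "set_size": len(set_members),
                    "overlap_count": k,
                    "p_value": min(p, 1.0),
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=[
                "community_id", "set_id", "community_size", "set_size",
                "overlap_count", "p_value", "padj", "enriched",
            ]
        )
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p_value"].to_numpy())
    table["enriched"] = table["padj"] < padj_threshold
    return table


def de_trend(members: Iterable[str], de_table: pd.DataFrame) -> dict:
    """Differential-expression trend of a gene collection.

    ``(n_over - n_under) / n_total`` where the classes come from the DE
    table; members missing from the table count as unclassified.  +1
    means every gene tends to overexpression, -1 underexpression, 0 an
    even split.
    """
    members = list(members)
    if not members:
        raise ValueError("empty community")
    cls = de_table["class"]
    n_over = sum(1 for g in members if g in cls.index and cls[g] == "over")
    n_under = sum(1 for g in members if g in cls.index and cls[g] == "under")
    n_total = len(members)
    return {
        "trend": (n_over - n_under) / n_total,
        "n_over": n_over,
        "n_under": n_under,
        "n_total": n_total,
    }


def shared_bp_matrix(
    enrichment: Mapping[str, pd.DataFrame],
    community_members: Mapping[str, Mapping[str, set]],
    de_tables: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Phenotype x biological-process trend matrix over shared processes.

    A process qualifies when enriched (per the tables' ``enriched`` flag)
    in every phenotype.  Each cell is the trend of the union of genes
    from all communities enriching that process in that phenotype,
    scored against the phenotype's DE table.  Returns an empty frame
    (with a ``warning`` attr) when no process is shared.
    """
    phenos = list(enrichment)
    if len(phenos) < 2:
        raise ValueError("need >= 2 phenotypes")
    enriched_sets = {
        ph: set(tab.loc[tab["enriched"], "set_id"]) for ph, tab in enrichment.items()
    }
    shared = set.intersection(*enriched_sets.values())
    if not shared:
        out = pd.DataFrame(index=phenos)
        out.attrs["warning"] = "no biological process enriched in every phenotype"
        return out
    mat = {}
    for bp in sorted(shared):
        col = {}
        for ph in phenos:
            tab = enrichment[ph]
            cids = tab.loc[tab["enriched"] & (tab["set_id"] == bp), "community_id"]
            genes: set = set()
            for cid in cids:
                genes |= set(community_members[ph][cid])
            col[ph] = de_trend(genes, de_tables[ph])["trend"]
        mat[bp] = col
    return pd.DataFrame(mat).loc[phenos]
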