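"""Network topology statistics: cis-fraction curves over rank cutoffs,
KS comparison of curves, biotype-pair fractions, component spectra and
k-way network intersections.

"Cis" means the two genes of an edge are annotated to the same chromosome
label; the cis-fraction curve tracks the share of cis edges among the
top-k strongest edges as k grows.  Cancer co-expression networks
concentrate cis edges at the top of the ranking far more than normal
tissue, and a two-sample KS test on the two curves quantifies the
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

from .io_formats import RankedEdgeList

__all__ = [
    "CisProfile",
    "default_cutoff_grid",
    "cis_fraction_curve",
    "ks_statistic",
    "ks_p_value",
    "ks_compare",
    "biotype_pair_fractions",
    "coarsen_biotype",
    "component_spectrum",
    "intersect_networks",
]


@dataclass
class CisProfile:
    """Cis-fraction values on an ascending grid of top-k cutoffs."""

    cutoffs: np.ndarray
    cis_fraction: np.ndarray
    network_id: str = ""
    # the curve points are serially dependent (nested top-k sets); any
    # test treating them as iid samples inherits that caveat
    caveat: str = field(
        default="cis-fraction points share edges across cutoffs (serially dependent)"
    )

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=np.int64)
        self.cis_fraction = np.asarray(self.cis_fraction, dtype=float)
        if len(self.cutoffs) != len(self.cis_fraction):
            raise ValueError("cutoffs and cis_fraction length mismatch")
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly increasing")
        if np.any((self.cis_fraction < 0) | (self.cis_fraction > 1)):
            raise ValueError("cis fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.cutoffs, "cis_fraction": self.cis_fraction}
        )


def default_cutoff_grid(n_edges: int, lo: int = 10_000, hi: int = 10_000_000,
                        n_points: int = 30) -> np.ndarray:
    """Logarithmic grid of top-k cutoffs from ``lo`` to ``min(hi, E)``."""
    hi = min(hi, n_edges)
    if hi <= lo:
        lo = max(1, hi // 10)
    grid = np.unique(
        np.round(np.logspace(np.log10(lo), np.log10(hi), n_points)).astype(np.int64)
    )
    return grid[grid >= 1]


def _cis_flags(edges: pd.DataFrame, annotation: pd.DataFrame) -> np.ndarray:
    nodes = set(edges["gene_a"]).union(edges["gene_b"])
    missing = sorted(g for g in nodes if g not in annotation.index)
    if missing:
        raise ValueError(f"edges reference unannotated genes: {missing[:10]}")
    chrom = annotation["chromosome"]
    return (
        chrom.loc[edges["gene_a"]].to_numpy() == chrom.loc[edges["gene_b"]].to_numpy()
    )


def cis_fraction_curve(
    edges: RankedEdgeList,
    annotation: pd.DataFrame,
    cutoffs: np.ndarray | list[int] | None = None,
    network_id: str = "",
) -> CisProfile:
    """Fraction of intra-chromosomal edges among the top-k, per cutoff k.

    Cutoffs beyond the number of edges are dropped.
    """
    df = edges.edges
    if cutoffs is None:
        cutoffs = default_cutoff_grid(len(df))
    cutoffs = np.asarray(sorted(set(int(c) for c in cutoffs)), dtype=np.int64)
    cutoffs = cutoffs[(cutoffs >= 1) & (cutoffs <= len(df))]
    if len(cutoffs) == 0:
        raise ValueError("no valid cutoffs within the edge list size")
    cum_cis = np.cumsum(_cis_flags(df, annotation))
    frac = cum_cis[cutoffs - 1] / cutoffs
    return CisProfile(cutoffs, frac, network_id)


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic, the sup of |ECDF_a - ECDF_b| over the
    pooled sample points."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / len(a)
    fb = np.searchsorted(b, pooled, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def ks_compare(profile_a: CisProfile, profile_b: CisProfile) -> tuple[float, float]:
    """Two-sample KS test on two cis-fraction curves.

    The two sets of cis-fraction values (one per cutoff) are treated as
    the two samples; D is the sup ECDF difference and the p-value uses
    the asymptotic Kolmogorov distribution.  The profile carries a caveat
    that the points are serially dependent.
    """
    a = profile_a.cis_fraction
    b = profile_b.cis_fraction
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ks_compare needs >= 2 points per profile")
    d = ks_statistic(a, b)
    return d, ks_p_value(d, len(a), len(b))


def ks_p_value(d: float, n: int, m: int) -> float:
    """Asymptotic two-sample KS p-value (Kolmogorov distribution) for a
    statistic ``d`` from samples of sizes ``n`` and ``m``."""
    if n < 1 or m < 1:
        raise ValueError("sample sizes must be positive")
    en = n * m / (n + m)
    return float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))


def coarsen_biotype(biotype: str) -> str:
    """Collapse fine biotypes into figure-legend families: any
    pseudogene sub-biotype -> ``pseudogene``, IG_* -> ``IG``,
    TR_* -> ``TR``; others unchanged."""
    if "pseudogene" in biotype:
        return "pseudogene"
    if biotype.startswith("IG_") or biotype == "IG":
        return "IG"
    if biotype.startswith("TR_") or biotype == "TR":
        return "TR"
    return biotype


def biotype_pair_fractions(
    edges: RankedEdgeList,
    annotation: pd.DataFrame,
    top_k: int | None = None,
    coarsen: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Share of the top-k edges per unordered biotype pair.

    Returns a DataFrame with columns biotype_a, biotype_b (sorted within
    row), count and fraction; fractions sum to 1.
    """
    df = edges.edges if top_k is None else edges.top(top_k)
    if df.empty:
        raise ValueError("no edges to tabulate")
    nodes = set(df["gene_a"]).union(df["gene_b"])
    missing = sorted(g for g in nodes if g not in annotation.index)
    if missing:
        raise ValueError(f"edges reference unannotated genes: {missing[:10]}")

    def fam(bt: str) -> str:
        if coarsen is not None and bt in coarsen:
            return coarsen[bt]
        return coarsen_biotype(bt)

    bt = annotation["biotype"].map(fam)
    ba = bt.loc[df["gene_a"]].to_numpy()
    bb = bt.loc[df["gene_b"]].to_numpy()
    lo = np.minimum(ba, bb)
    hi = np.maximum(ba, bb)
    tab = (
        pd.DataFrame({"biotype_a": lo, "biotype_b": hi})
        .value_counts()
        .rename("count")
        .reset_index()
    )
    tab["fraction"] = tab["count"] / tab["count"].sum()
    return tab.sort_values("fraction", ascending=False).reset_index(drop=True)


def component_spectrum(
    edges: RankedEdgeList,
    top_k: int | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Connected components of the top-k graph, sizes descending.

    With an annotation, each component also reports its chromosome purity
    (fraction of members on the modal chromosome) and the modal label.
    Returns columns component_id, size, members(;-joined) [, modal_chromosome,
    purity].
    """
    df = edges.edges if top_k is None else edges.top(top_k)
    g = nx.Graph()
    g.add_edges_from(zip(df["gene_a"], df["gene_b"]))
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)[0]))
    rows = []
    for i, comp in enumerate(comps, start=1):
        members = sorted(comp)
        row = {
            "component_id": f"comp{i}",
            "size": len(members),
            "members": ";".join(members),
        }
        if annotation is not None:
            chroms = annotation.loc[members, "chromosome"]
            counts = chroms.value_counts()
            row["modal_chromosome"] = counts.index[0]
            row["purity"] = float(counts.iloc[0] / len(members))
        rows.append(row)
    return pd.DataFrame(rows)


def intersect_networks(
    edge_lists: list[RankedEdgeList], top_k: int = 100_000
) -> tuple[set[tuple[str, str]], set[str]]:
    """Edges common to the top-k of every input network.

    Exact set intersection over canonical (gene_a, gene_b) pairs; the
    node set contains only endpoints of surviving edges.  Order of the
    inputs is irrelevant.
    """
    if len(edge_lists) < 2:
        raise ValueError("intersection needs at least 2 networks")
    common: set[tuple[str, str]] | None = None
    for el in edge_lists:
        s = el.edge_set(top_k)
        common = s if common is None else (common & s)
    nodes = {g for pair in common for g in pair}
    return common, nodes
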