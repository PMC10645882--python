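"""Persistent community detection over a Louvain resolution sweep.

The approach follows the persistent-homology framing popularized by
HiDeF: run modularity-based Louvain at many resolution settings, match
communities at adjacent resolutions by Jaccard similarity of member
sets, collapse matched chains into one consensus community, and retain
only communities whose chain spans at least ``min_persistence``
consecutive resolutions.  Containment links between retained communities
give the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Community",
    "CommunityHierarchy",
    "default_resolutions",
    "resolution_sweep",
    "persistence_filter",
    "community_table",
    "detect_communities",
]


@dataclass
class Community:
    community_id: str
    members: frozenset
    persistence: int
    resolution_range: tuple[float, float]


@dataclass
class CommunityHierarchy:
    communities: list[Community]
    containment_links: list[tuple[str, str]] = field(default_factory=list)  # parent -> child
    resolutions_swept: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.communities)

    def by_id(self) -> dict[str, Community]:
        return {c.community_id: c for c in self.communities}


def default_resolutions(n: int = 20, lo: float = 0.25, hi: float = 4.0) -> list[float]:
    """Log-spaced resolution sweep bracketing gamma = 1 symmetrically."""
    return list(np.logspace(np.log10(lo), np.log10(hi), n))


def _as_graph(graph) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    g = nx.Graph()
    g.add_edges_from((a, b) for a, b in graph)
    return g


def resolution_sweep(
    graph, resolutions: list[float] | None = None, seed: int = 0
) -> tuple[list[list[frozenset]], list[float]]:
    """One seeded Louvain partition per resolution value.

    ``graph`` is a networkx Graph or an iterable of (gene_a, gene_b)
    pairs.  Deterministic for a fixed seed: the seed fixes Louvain's node
    shuffling at every resolution.
    """
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if resolutions is None:
        resolutions = default_resolutions()
    partitions = []
    for i, gamma in enumerate(resolutions):
        comms = nx.community.louvain_communities(
            g, resolution=float(gamma), seed=int(seed) + i
        )
        partitions.append([frozenset(c) for c in comms])
    return partitions, list(resolutions)


def _jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def persistence_filter(
    partitions: list[list[frozenset]],
    resolutions: list[float] | None = None,
    jaccard_threshold: float = 0.75,
    min_persistence: int = 5,
    min_size: int = 5,
) -> CommunityHierarchy:
    """Collapse a resolution sweep into persistent consensus communities.

    Communities at adjacent resolutions are matched greedily by highest
    Jaccard >= ``jaccard_threshold`` (one-to-one).  Each matched chain
    becomes one community whose members are the genes present in at
    least half of the chain's snapshots; its persistence is the chain
    length.  Chains shorter than ``min_persistence`` and consensus sets
    smaller than ``min_size`` are dropped,
    duplicates merged (max persistence wins), and containment links
    recorded wherever one retained member set is a proper subset of
    another (transitively reduced).
    """
    if not 0.0 < jaccard_threshold <= 1.0:
        raise ValueError("jaccard_threshold must be in (0, 1]")
    if min_persistence > len(partitions):
        raise ValueError(
            f"min_persistence={min_persistence} exceeds the number of "
            f"partitions ({len(partitions)})"
        )
    if resolutions is None:
        resolutions = list(range(len(partitions)))

    # chains: list of dicts {snapshots: [frozenset...], start: idx, open: bool}
    chains: list[dict] = []
    active: list[int] = []  # indices into chains
    for t, part in enumerate(partitions):
        if t == 0:
            for c in part:
                chains.append({"snapshots": [c], "start": 0})
            active = list(range(len(chains)))
            continue
        # candidate matches between active chain heads and new communities
        cands = []
        for ci_pos, ci in enumerate(active):
            head = chains[ci]["snapshots"][-1]
            for cj, comm in enumerate(part):
                j = _jaccard(head, comm)
                if j >= jaccard_threshold:
                    cands.append((j, ci_pos, cj))
        cands.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_chain: set[int] = set()
        used_comm: set[int] = set()
        matched_pairs = []
        for j, ci_pos, cj in cands:
            if ci_pos in used_chain or cj in used_comm:
                continue
            used_chain.add(ci_pos)
            used_comm.add(cj)
            matched_pairs.append((ci_pos, cj))
        new_active = []
        for ci_pos, cj in matched_pairs:
            ci = active[ci_pos]
            chains[ci]["snapshots"].append(part[cj])
            new_active.append(ci)
        for cj, comm in enumerate(part):
            if cj not in used_comm:
                chains.append({"snapshots": [comm], "start": t})
                new_active.append(len(chains) - 1)
        active = sorted(new_active)

    # consensus + persistence per chain
    retained: dict[frozenset, tuple[int, tuple[float, float]]] = {}
    for ch in chains:
        snaps = ch["snapshots"]
        persistence = len(snaps)
        if persistence < min_persistence:
            continue
        counts: dict = {}
        for s in snaps:
            for gene in s:
                counts[gene] = counts.get(gene, 0) + 1
        consensus = frozenset(g for g, c in counts.items() if c * 2 >= persistence)
        if len(consensus) < min_size:
            continue
        r0 = resolutions[ch["start"]]
        r1 = resolutions[ch["start"] + persistence - 1]
        prev = retained.get(consensus)
        if prev is None or persistence > prev[0]:
            retained[consensus] = (persistence, (float(r0), float(r1)))

    ordered = sorted(retained.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])[0]))
    communities = [
        Community(f"C{i + 1:04d}", members, pers, rng)
        for i, (members, (pers, rng)) in enumerate(ordered)
    ]

    # containment: proper-subset relations, transitively reduced
    links = []
    for parent in communities:
        for child in communities:
            if child.members < parent.members:
                links.append((parent.community_id, child.community_id))
    direct = []
    members = {c.community_id: c.members for c in communities}
    link_set = set(links)
    for p, c in links:
        if not any(
            (p, mid) in link_set and (mid, c) in link_set
            for mid in members
            if mid not in (p, c)
        ):
            direct.append((p, c))
    return CommunityHierarchy(communities, direct, list(map(float, resolutions)))


def community_table(hierarchy: CommunityHierarchy) -> pd.DataFrame:
    """Flat table for the enrichment stage: one row per community."""
    if not hierarchy.communities:
        raise ValueError("empty community hierarchy")
    rows = [
        {
            "community_id": c.community_id,
            "size": len(c.members),
            "persistence": c.persistence,
            "resolution_min": c.resolution_range[0],
            "resolution_max": c.resolution_range[1],
            "members": ";".join(sorted(c.members)),
        }
        for c in hierarchy.communities
    ]
    return pd.DataFrame(rows)


def detect_communities(
    graph,
    resolutions: list[float] | None = None,
    jaccard_threshold: float = 0.75,
    min_persistence: int = 5,
    min_size: int = 5,
    seed: int = 0,
) -> CommunityHierarchy:
    """Sweep + persistence filter in one call."""
    partitions, res = resolution_sweep(graph, resolutions, seed)
    return persistence_filter(
        partitions, res, jaccard_threshold, min_persistence, min_size
    )
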