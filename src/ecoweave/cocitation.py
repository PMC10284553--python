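"""Co-citation networks and their community structure.

References are nodes; the weight of an edge counts how many article
reference lists contain both endpoints.  The most co-cited references (by
total co-citation strength, i.e. weighted degree) form the subnetwork that
is clustered with the Louvain modularity-maximization algorithm; a
robustness sweep reruns the clustering across subnetwork sizes and scores
the stability of the partitions with the adjusted Rand index on shared
nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity
from sklearn.metrics import adjusted_rand_score

from .corpus import Corpus

__all__ = [
    "CocitationGraph",
    "Clustering",
    "build_cocitation",
    "top_n_subgraph",
    "louvain",
    "robustness_sweep",
]


@dataclass(frozen=True)
class CocitationGraph:
    """Weighted reference co-citation network (no self-loops)."""

    graph: nx.Graph

    @property
    def strengths(self) -> pd.Series:
        s = {
            v: float(sum(d["weight"] for _, _, d in self.graph.edges(v, data=True)))
            for v in self.graph.nodes
        }
        return pd.Series(s, name="strength").sort_values(ascending=False)

    @property
    def citation_counts(self) -> pd.Series:
        counts = nx.get_node_attributes(self.graph, "citations")
        return pd.Series(counts, name="citations", dtype=float)


@dataclass(frozen=True)
class Clustering:
    """Community partition of a graph with its weighted modularity Q."""

    communities: dict  # node -> community id
    Q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.communities.values()))

    def sizes(self) -> pd.Series:
        return pd.Series(self.communities).value_counts().sort_index()


def build_cocitation(corpus: Corpus | list, group: str | None = "complexity") -> CocitationGraph:
    """Build the weighted co-citation network from article reference lists.

    Each article contributes +1 to the weight of every unordered pair of
    distinct references in its list (duplicate keys within one list count
    once).  ``group`` restricts to one article group (the analysis uses the
    complexity articles); pass ``None`` to use the whole corpus.  The node
    attribute ``citations`` records how many lists cite each reference.
    """
    if isinstance(corpus, Corpus):
        articles = [a for a in corpus if group is None or a.group == group]
        ref_lists = [a.references for a in articles]
    else:
        ref_lists = list(corpus)
    g = nx.Graph()
    any_refs = False
    for refs in ref_lists:
        uniq = sorted(dict.fromkeys(refs))
        if not uniq:
            continue
        any_refs = True
        for r in uniq:
            if g.has_node(r):
                g.nodes[r]["citations"] += 1
            else:
                g.add_node(r, citations=1)
        for a, b in itertools.combinations(uniq, 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    if not any_refs:
        raise ValueError("no references anywhere in the corpus")
    if g.number_of_edges() == 0:
        raise ValueError("no co-citations: every reference list has a single entry")
    return CocitationGraph(graph=g)


def top_n_subgraph(g: CocitationGraph, n: int = 100, by: str = "strength") -> CocitationGraph:
    """Induced subgraph on the n most co-cited references.

    Ranking is by total co-citation strength (weighted degree) by default,
    or by raw citation count with ``by="citations"``; ties are broken
    lexicographically by citation key so the selection is deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if by not in ("strength", "citations"):
        raise ValueError(f"unknown ranking {by!r}")
    score = g.strengths if by == "strength" else g.citation_counts
    ranked = sorted(score.items(), key=lambda kv: (-kv[1], kv[0]))
    keep = [k for k, _ in ranked[:n]]
    return CocitationGraph(graph=g.graph.subgraph(keep).copy())


def louvain(g: CocitationGraph | nx.Graph, seed: int = 0) -> Clustering:
    """Louvain community detection on a weighted graph.

    Greedy modularity optimization with node-order shuffling controlled by
    ``seed``; disconnected components are handled independently by the
    algorithm.  Returns the partition and its weighted modularity
    Q = sum_c (e_c/m - (d_c/2m)^2).
    """
    graph = g.graph if isinstance(g, CocitationGraph) else g
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = louvain_communities(graph, weight="weight", seed=seed)
    q = modularity(graph, comms, weight="weight")
    mapping = {}
    for cid, members in enumerate(sorted(comms, key=lambda c: sorted(map(str, c))[0])):
        for v in members:
            mapping[v] = cid
    return Clustering(communities=mapping, Q=float(q))


def robustness_sweep(
    g: CocitationGraph, n_values: list[int], seed: int = 0
) -> pd.DataFrame:
    """Rerun top-n selection + Louvain across subnetwork sizes.

    Returns one row per n with the community count, modularity, and the
    adjusted Rand index between this partition and the previous one,
    computed on the nodes the two subnetworks share (NaN for the first n).
    A sweep that dips below the planted structure size degrades the ARI but
    is not an error.
    """
    rows = []
    partitions: list[dict] = []
    for i, n in enumerate(n_values):
        sub = top_n_subgraph(g, n=n)
        clust = louvain(sub, seed=seed)
        ari = np.nan
        if i > 0:
            prev = partitions[-1]
            shared = sorted(set(prev) & set(clust.communities))
            if len(shared) >= 2:
                ari = adjusted_rand_score(
                    [prev[v] for v in shared],
                    [clust.communities[v] for v in shared],
                )
        partitions.append(clust.communities)
        rows.append(
            {
                "n": n,
                "n_communities": clust.n_communities,
                "Q": clust.Q,
                "ari_vs_previous": ari,
            }
        )
    return pd.DataFrame(rows)
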