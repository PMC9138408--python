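"""Interaction-network construction and Maximal Clique Centrality hub ranking.

Networks are undirected simple graphs over gene symbols with per-edge
confidence in [0, 1] (STRING combined-score convention). Edges are kept when
confidence >= 0.4 by default; confidences are used only for thresholding,
never as weights.

MCC(v) sums (|C| - 1)! over the maximal cliques C containing v. When v's
neighborhood contains no internal edge the definition degenerates to the
node's degree (each neighbor forms a maximal 2-clique, so the sum equals the
degree; the convention is stated explicitly because cytoHubba documents it
as a special case). Isolated nodes score 0. Clique enumeration is
Bron-Kerbosch with pivoting (networkx ``find_cliques``), which copes with the
thousand-node converged interactomes as well as the ~100-gene signature
networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import DataFormatError

DEFAULT_CONFIDENCE_CUTOFF = 0.4


def build_network(
    edges: Iterable[tuple[str, str, float]],
    node_universe: Iterable[str],
    confidence_cutoff: float = DEFAULT_CONFIDENCE_CUTOFF,
) -> nx.Graph:
    """Confidence-filtered simple graph restricted to a gene universe.

    Keeps edges with confidence >= ``confidence_cutoff`` whose both
    endpoints lie in ``node_universe``; self-loops are dropped, duplicate
    pairs keep the maximal confidence, and nodes without any retained edge
    are not part of the network.
    """
    universe = {str(g).upper() for g in node_universe}
    if not universe:
        raise DataFormatError("empty node universe")
    g = nx.Graph()
    for a, b, conf in edges:
        a, b = str(a).upper(), str(b).upper()
        if not 0 <= conf <= 1:
            raise DataFormatError(f"confidence {conf} outside [0, 1]")
        if a == b or a not in universe or b not in universe:
            continue
        if conf < confidence_cutoff:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    return g


def enumerate_maximal_cliques(net: nx.Graph) -> list[frozenset[str]]:
    """All maximal cliques (Bron-Kerbosch with pivoting)."""
    return [frozenset(c) for c in nx.find_cliques(net)]


@dataclass(frozen=True)
class HubRanking:
    """MCC scores plus a total, reproducible ordering.

    Ties are broken by higher degree, then lexicographically smaller gene
    symbol.
    """

    mcc: Mapping[str, int]
    degree: Mapping[str, int]

    @property
    def ordered(self) -> list[str]:
        return sorted(
            self.mcc,
            key=lambda g: (-self.mcc[g], -self.degree[g], g),
        )

    def as_rows(self) -> list[tuple[str, int, int, int]]:
        """(gene, mcc, degree, rank) rows in rank order."""
        return [
            (g, self.mcc[g], self.degree[g], r)
            for r, g in enumerate(self.ordered, start=1)
        ]


def mcc_scores(net: nx.Graph) -> HubRanking:
    """Maximal Clique Centrality of every node.

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!. A node
    whose neighborhood has no internal edge scores its degree (equivalent
    under the sum, asserted here as the explicit star-case convention);
    isolated nodes score 0.
    """
    scores: dict[str, int] = {v: 0 for v in net.nodes}
    degree = {v: int(d) for v, d in net.degree()}
    for clique in nx.find_cliques(net):
        contrib = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    for v in net.nodes:
        if degree[v] == 0:
            scores[v] = 0
            continue
        nbrs = list(net.neighbors(v))
        has_internal = any(
            net.has_edge(u, w)
            for i, u in enumerate(nbrs)
            for w in nbrs[i + 1 :]
        )
        if not has_internal:
            scores[v] = degree[v]  # star case: no edge among neighbors
    return HubRanking(mcc=scores, degree=degree)


def top_hubs(ranking: HubRanking, k: int = 10) -> list[str]:
    """The k highest-MCC genes (all genes if fewer than k)."""
    if k < 1:
        raise DataFormatError(f"k must be >= 1, got {k}")
    if not ranking.mcc:
        raise DataFormatError("empty hub ranking")
    return ranking.ordered[:k]


def hub_subnetwork(net: nx.Graph, hubs: Sequence[str]) -> nx.Graph:
    """Union of all tied shortest paths between every hub pair.

    Unweighted BFS shortest paths; every node and edge lying on any tied
    shortest path between two hubs is included. Hubs with no path to any
    other hub are kept as isolated nodes flagged ``isolated_hub=True``.
    """
    if not hubs:
        raise DataFormatError("empty hub list")
    hubs = [str(h).upper() for h in hubs]
    missing = [h for h in hubs if h not in net.nodes]
    if missing:
        raise DataFormatError(f"hubs not in network: {missing}")
    sub = nx.Graph()
    connected: set[str] = set()
    for i, a in enumerate(hubs):
        for b in hubs[i + 1 :]:
            if not nx.has_path(net, a, b):
                continue
            connected.update((a, b))
            for path in nx.all_shortest_paths(net, a, b):
                for u, w in zip(path, path[1:]):
                    sub.add_edge(u, w, **net[u][w])
    for h in hubs:
        if h not in sub.nodes:
            sub.add_node(h, isolated_hub=True)
        elif h not in connected:
            sub.nodes[h]["isolated_hub"] = True
    return sub


def network_to_edges(net: nx.Graph) -> list[tuple[str, str, float]]:
    """Sorted (a, b, confidence) triples for serialization."""
    out = []
    for a, b, data in net.edges(data=True):
        a, b = sorted((a, b))
        out.append((a, b, float(data.get("confidence", 1.0))))
    return sorted(out)
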