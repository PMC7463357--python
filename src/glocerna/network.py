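"""ceRNA network construction and topology.

The functional pairs form a bipartite graph (lncRNA nodes on one side,
PCG nodes on the other). Degree and unnormalized betweenness centrality
rank hub ce-lncRNAs; pairwise shared-PCG counts measure lncRNA
similarity; intersecting two cohorts' networks yields a conservative
network with hypergeometric overlap significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .exceptions import ConsistencyError, ValidationError
from .types import LNCRNA, PCG


def build_network(results: pd.DataFrame) -> nx.Graph:
    """Bipartite graph of the functional pairs of a scored result table.

    Node attribute ``kind`` is ``"lncRNA"`` or ``"PCG"``; duplicate rows
    collapse to a single edge.
    """
    g = nx.Graph()
    if len(results):
        functional = results.loc[results["functional"]]
        for lnc, pcg in zip(functional["lncrna_id"], functional["pcg_id"]):
            if lnc == pcg:
                raise ValidationError(f"self-loop on {lnc!r}")
            g.add_node(lnc, kind=LNCRNA)
            g.add_node(pcg, kind=PCG)
            g.add_edge(lnc, pcg)
    return g


def network_from_edges(edges) -> nx.Graph:
    """Build a ceRNA network directly from (lncrna_id, pcg_id) edges."""
    g = nx.Graph()
    for lnc, pcg in edges:
        g.add_node(lnc, kind=LNCRNA)
        g.add_node(pcg, kind=PCG)
        g.add_edge(lnc, pcg)
    return g


def lncrna_nodes(net: nx.Graph) -> set[str]:
    return {n for n, d in net.nodes(data=True) if d.get("kind") == LNCRNA}


def pcg_nodes(net: nx.Graph) -> set[str]:
    return {n for n, d in net.nodes(data=True) if d.get("kind") == PCG}


def node_degree(net: nx.Graph) -> dict[str, int]:
    """Number of links of every node."""
    return dict(net.degree())


def node_betweenness(net: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness centrality on the undirected graph: for
    each node v, the sum over unordered pairs (s, t != v) of the fraction
    of shortest s-t paths passing through v."""
    return nx.betweenness_centrality(net, normalized=False)


def topology_table(net: nx.Graph) -> pd.DataFrame:
    """Degree and betweenness of every node, sorted by id."""
    deg = node_degree(net)
    btw = node_betweenness(net)
    rows = [
        {
            "node": n,
            "kind": net.nodes[n].get("kind", ""),
            "degree": deg[n],
            "betweenness": btw[n],
        }
        for n in sorted(net.nodes)
    ]
    return pd.DataFrame(rows, columns=["node", "kind", "degree", "betweenness"])


def lncrna_similarity(net: nx.Graph) -> pd.DataFrame:
    """Pairwise shared-PCG counts and Jaccard index between lncRNAs.

    One row per unordered lncRNA pair (a < b lexicographically); both the
    raw shared count and the union-normalized Jaccard are reported.
    """
    lncs = sorted(lncrna_nodes(net))
    rows = []
    neigh = {l: set(net.neighbors(l)) for l in lncs}
    for i, a in enumerate(lncs):
        for b in lncs[i + 1 :]:
            shared = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            rows.append(
                {
                    "lncrna_a": a,
                    "lncrna_b": b,
                    "shared_pcg_count": shared,
                    "jaccard": shared / union if union else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["lncrna_a", "lncrna_b", "shared_pcg_count", "jaccard"]
    )


@dataclass
class NetworkOverlap:
    """Shared lncRNA/PCG/edge counts between two networks with upper-tail
    hypergeometric significance against stated universes."""

    shared_lncrnas: int
    shared_pcgs: int
    shared_edges: int
    p_lncrnas: float
    p_pcgs: float
    p_edges: float


def _overlap_p(n_a: int, n_b: int, shared: int, universe: int) -> float:
    """P(X >= shared) drawing n_a items from `universe` with n_b successes."""
    if universe < max(n_a, n_b):
        raise ConsistencyError(
            f"universe {universe} smaller than observed sets ({n_a}, {n_b})"
        )
    return float(min(hypergeom.sf(shared - 1, universe, n_b, n_a), 1.0))


def intersect_networks(
    net_a: nx.Graph,
    net_b: nx.Graph,
    universes: dict[str, int],
) -> tuple[nx.Graph, NetworkOverlap]:
    """Conservative network (shared edges) and overlap significance.

    ``universes`` supplies the candidate counts under keys ``lncrnas``,
    ``pcgs`` and ``edges`` (e.g. the candidates scoreable in both
    cohorts); each overlap p-value is the upper-tail hypergeometric
    probability of at least the observed intersection.
    """
    lnc_a, lnc_b = lncrna_nodes(net_a), lncrna_nodes(net_b)
    pcg_a, pcg_b = pcg_nodes(net_a), pcg_nodes(net_b)
    edges_a = {frozenset(e) for e in net_a.edges}
    edges_b = {frozenset(e) for e in net_b.edges}
    shared_edges = edges_a & edges_b

    overlap = NetworkOverlap(
        shared_lncrnas=len(lnc_a & lnc_b),
        shared_pcgs=len(pcg_a & pcg_b),
        shared_edges=len(shared_edges),
        p_lncrnas=_overlap_p(
            len(lnc_a), len(lnc_b), len(lnc_a & lnc_b), universes["lncrnas"]
        ),
        p_pcgs=_overlap_p(
            len(pcg_a), len(pcg_b), len(pcg_a & pcg_b), universes["pcgs"]
        ),
        p_edges=_overlap_p(
            len(edges_a), len(edges_b), len(shared_edges), universes["edges"]
        ),
    )
    conservative = network_from_edges(
        sorted(
            (a, b) if net_a.nodes[a].get("kind") == LNCRNA else (b, a)
            for a, b in (tuple(e) for e in shared_edges)
        )
    )
    return conservative, overlap


def extract_subnetwork(net: nx.Graph, seed_lncrnas) -> nx.Graph:
    """First-neighbor subnetwork of the given seed lncRNAs: the seeds,
    their PCG neighbors, and only the seed-neighbor edges."""
    lncs = lncrna_nodes(net)
    seeds = [s for s in seed_lncrnas if s in lncs]
    sub = nx.Graph()
    for s in seeds:
        sub.add_node(s, kind=LNCRNA)
        for nb in net.neighbors(s):
            sub.add_node(nb, kind=PCG)
            sub.add_edge(s, nb)
    return sub


def edge_table(net: nx.Graph) -> pd.DataFrame:
    """Edge list with the lncRNA in the first column, sorted."""
    rows = []
    for a, b in net.edges:
        lnc, pcg = (a, b) if net.nodes[a].get("kind") == LNCRNA else (b, a)
        rows.append({"lncrna_id": lnc, "pcg_id": pcg})
    df = pd.DataFrame(rows, columns=["lncrna_id", "pcg_id"])
    return df.sort_values(["lncrna_id", "pcg_id"], kind="mergesort").reset_index(
        drop=True
    )
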