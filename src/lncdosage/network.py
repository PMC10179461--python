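"""lncRNA-mRNA interaction networks and hub ranking by maximal clique centrality.

The graph is built from predicted target pairs: one node per gene (typed
lncRNA or mRNA), one edge per distinct pair, so the network is simple and
bipartite.  A consequence worth knowing: in a bipartite graph every
maximal clique is a single edge, hence MCC(v) equals the degree of v, the
neighbourhood of any node induces no edges (DMNC = 0) and its largest
neighbour component is a single node (MNC = 1).

Centrality definitions (one per column of the standard hub table):

* MCC(v)        = sum over maximal cliques C containing v, |C| >= 2, of (|C|-1)!
* DMNC(v)       = E/N**eps of the largest component of the subgraph induced
                  by N(v) (eps = 1.7); 0 if that subgraph has no edges
* MNC(v)        = node count of that largest component
* Degree        = graph degree
* EPC(v)        = mean component size of v over random edge percolations
                  (each edge kept with probability 0.5)
* Bottleneck(v) = number of BFS shortest-path trees (one rooted at every
                  node of v's component, lexicographic parent tie-break)
                  in which v's subtree exceeds a quarter of the component
* Eccentricity  = 1/ecc(v) within v's component (0 for isolated nodes)
* Closeness     = harmonic: sum of 1/d(v,u) over reachable u
* Radiality     = sum of (diameter + 1 - d(v,u)) / (n_comp - 1)
* Betweenness   = Freeman shortest-path betweenness (unnormalised)
* Stress        = number of shortest paths passing through v
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .targets import TargetPair

__all__ = [
    "CentralityConfig",
    "build_network",
    "maximal_cliques",
    "mcc",
    "centrality_suite",
    "select_hubs",
    "summarize_target_regulation",
    "write_sif",
    "read_sif",
]

TABLE_COLUMNS = [
    "MCC",
    "DMNC",
    "MNC",
    "Degree",
    "EPC",
    "Bottleneck",
    "Eccentricity",
    "Closeness",
    "Radiality",
    "Betweenness",
    "Stress",
]


@dataclass
class CentralityConfig:
    dmnc_epsilon: float = 1.7
    epc_iterations: int = 1000
    epc_keep_prob: float = 0.5
    bottleneck_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.epc_keep_prob < 1:
            raise ValueError("epc_keep_prob must be in (0, 1)")
        if self.epc_iterations < 1:
            raise ValueError("epc_iterations must be >= 1")


def build_network(pairs: Iterable[TargetPair]) -> nx.Graph:
    """Simple bipartite graph from target pairs; nodes carry kind=lncRNA|mRNA."""
    g = nx.Graph()
    for p in pairs:
        if p.lncrna_id == p.target_id:
            raise ValueError(f"pair with identical endpoints: {p.lncrna_id!r}")
        g.add_node(p.lncrna_id, kind="lncRNA")
        g.add_node(p.target_id, kind="mRNA")
        g.add_edge(p.lncrna_id, p.target_id)
    kinds = nx.get_node_attributes(g, "kind")
    for u, v in g.edges:
        if kinds[u] == kinds[v]:
            raise ValueError(f"gene {u if kinds[u] == 'lncRNA' else v!r} appears on both sides of a pair")
    return g


def maximal_cliques(g: nx.Graph) -> list[tuple]:
    """All maximal cliques of size >= 2, via Bron-Kerbosch with pivoting.

    Output is deterministic: each clique is a sorted tuple and the list is
    sorted lexicographically.
    """
    adj = {v: set(g.neighbors(v)) - {v} for v in g.nodes}
    cliques: list[tuple] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            if len(r) >= 2:
                cliques.append(tuple(sorted(r)))
            return
        pivot = max(p | x, key=lambda u: len(adj[u] & p))
        for v in sorted(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(adj), set())
    return sorted(cliques)


def mcc(g: nx.Graph) -> dict:
    """Maximal clique centrality: MCC(v) = sum over cliques C with v of (|C|-1)!."""
    scores = {v: 0 for v in g.nodes}
    for clique in maximal_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def _neighborhood_components(g: nx.Graph, v) -> list[set]:
    sub = g.subgraph(g.neighbors(v))
    return [set(c) for c in nx.connected_components(sub)] if sub.number_of_nodes() else []


def _mnc_dmnc(g: nx.Graph, epsilon: float) -> tuple[dict, dict]:
    mnc, dmnc = {}, {}
    for v in g.nodes:
        comps = _neighborhood_components(g, v)
        if not comps:
            mnc[v], dmnc[v] = 0, 0.0
            continue
        sub = g.subgraph(g.neighbors(v))
        best = max(comps, key=lambda c: (len(c), sorted(c)))
        mnc[v] = len(best)
        edges = sub.subgraph(best).number_of_edges()
        dmnc[v] = edges / len(best) ** epsilon if edges else 0.0
    return mnc, dmnc


def _epc(g: nx.Graph, config: CentralityConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = sorted((index[u], index[v]) for u, v in g.edges)
    totals = np.zeros(len(nodes))
    parent = np.empty(len(nodes), dtype=np.int64)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for _ in range(config.epc_iterations):
        keep = rng.random(len(edges)) < config.epc_keep_prob
        parent[:] = np.arange(len(nodes))
        for (u, v), k in zip(edges, keep):
            if k:
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
        roots = np.fromiter((find(i) for i in range(len(nodes))), dtype=np.int64)
        sizes = np.bincount(roots, minlength=len(nodes))
        totals += sizes[roots]
    return {v: totals[index[v]] / config.epc_iterations for v in nodes}


def _bfs_layers(adj: Mapping, order: Sequence, source):
    """BFS distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    nxt.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        frontier = nxt
    return dist, sigma


def _component_matrices(g: nx.Graph, comp: list):
    index = {v: i for i, v in enumerate(comp)}
    adj = {v: sorted(g.neighbors(v)) for v in comp}
    n = len(comp)
    D = np.zeros((n, n), dtype=np.int64)
    S = np.zeros((n, n), dtype=float)
    for v in comp:
        dist, sigma = _bfs_layers(adj, comp, v)
        for w, d in dist.items():
            D[index[v], index[w]] = d
            S[index[v], index[w]] = sigma[w]
    return index, D, S


def _stress_from_matrices(D: np.ndarray, S: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    stress = np.zeros(n)
    iu = np.triu_indices(n, k=1)
    for v in range(n):
        on_path = (D[:, v][:, None] + D[v, :][None, :]) == D
        contrib = S[:, v][:, None] * S[v, :][None, :]
        mat = np.where(on_path, contrib, 0.0)
        mat[v, :] = 0.0
        mat[:, v] = 0.0
        stress[v] = mat[iu].sum()
    return stress


def _bottleneck_trees(g: nx.Graph, comp: list, fraction: float) -> dict:
    """Score BFS shortest-path trees: +1 when v's subtree exceeds fraction*n."""
    scores = {v: 0 for v in comp}
    n = len(comp)
    threshold = fraction * n
    adj = {v: sorted(g.neighbors(v)) for v in comp}
    for root in comp:
        dist, _ = _bfs_layers(adj, comp, root)
        # lexicographically smallest neighbour one level up becomes the parent
        parent = {}
        for v in comp:
            if v == root:
                continue
            parent[v] = min(w for w in adj[v] if dist[w] == dist[v] - 1)
        size = {v: 1 for v in comp}
        for v in sorted(comp, key=lambda u: dist[u], reverse=True):
            if v != root:
                size[parent[v]] += size[v]
        for v in comp:
            if v != root and size[v] > threshold:
                scores[v] += 1
    return scores


def centrality_suite(g: nx.Graph, config: CentralityConfig | None = None) -> pd.DataFrame:
    """Compute all eleven centrality metrics for every node.

    The result has one row per node, the standard hub-table column order,
    and is sorted by MCC descending (ties: Degree descending, then node
    name).  EPC uses the seeded RNG from ``config``; everything else is
    deterministic.
    """
    config = config or CentralityConfig()
    nodes = sorted(g.nodes)
    mcc_scores = mcc(g)
    mnc, dmnc = _mnc_dmnc(g, config.dmnc_epsilon)
    epc = _epc(g, config)
    betweenness = nx.betweenness_centrality(g, normalized=False)

    ecc = {v: 0.0 for v in nodes}
    closeness = {v: 0.0 for v in nodes}
    radiality = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    bottleneck = {v: 0 for v in nodes}
    for comp_set in nx.connected_components(g):
        comp = sorted(comp_set)
        n = len(comp)
        if n == 1:
            continue
        index, D, S = _component_matrices(g, comp)
        diam = int(D.max())
        st = _stress_from_matrices(D, S)
        for v in comp:
            i = index[v]
            row = D[i]
            e = int(row.max())
            ecc[v] = 1.0 / e if e else 0.0
            mask = np.arange(n) != i
            closeness[v] = float((1.0 / row[mask]).sum())
            radiality[v] = float((diam + 1 - row[mask]).sum() / (n - 1))
            stress[v] = float(st[i])
        bn = _bottleneck_trees(g, comp, config.bottleneck_fraction)
        bottleneck.update(bn)

    table = pd.DataFrame(
        {
            "MCC": [mcc_scores[v] for v in nodes],
            "DMNC": [dmnc[v] for v in nodes],
            "MNC": [mnc[v] for v in nodes],
            "Degree": [g.degree(v) for v in nodes],
            "EPC": [epc[v] for v in nodes],
            "Bottleneck": [bottleneck[v] for v in nodes],
            "Eccentricity": [ecc[v] for v in nodes],
            "Closeness": [closeness[v] for v in nodes],
            "Radiality": [radiality[v] for v in nodes],
            "Betweenness": [betweenness[v] for v in nodes],
            "Stress": [stress[v] for v in nodes],
        },
        index=pd.Index(nodes, name="Node_Name"),
    )
    table = table.sort_values(
        by=["MCC", "Degree", "Node_Name"], ascending=[False, False, True], kind="mergesort"
    )
    return table[TABLE_COLUMNS]


def select_hubs(
    table: pd.DataFrame, min_mcc: float = 30, graph: nx.Graph | None = None
) -> tuple[list, nx.Graph | None]:
    """Hub nodes with MCC >= min_mcc (inclusive) and their induced subnetwork.

    If a graph with ``kind`` node attributes is supplied, only lncRNA
    nodes are eligible as hubs and the returned subnetwork contains the
    hubs plus all their neighbours; otherwise selection is on MCC alone
    and no subnetwork is built.
    """
    if table.empty:
        return [], None
    kinds = nx.get_node_attributes(graph, "kind") if graph is not None else {}
    hubs = [
        v
        for v in table.index
        if table.at[v, "MCC"] >= min_mcc and (not kinds or kinds.get(v) == "lncRNA")
    ]
    sub = None
    if graph is not None:
        members = set(hubs)
        for h in hubs:
            members.update(graph.neighbors(h))
        sub = graph.subgraph(members).copy()
    return hubs, sub


def summarize_target_regulation(status_by_target: Mapping[str, Iterable[str] | str]) -> dict:
    """Aggregate per-target DE statuses into the up/down/both/ns breakdown.

    Each target maps to one status or a collection of statuses (a gene can
    be targeted by both up- and down-regulated partners).  Returns counts
    per category and their total.
    """
    counts = {"n_down": 0, "n_up": 0, "n_both": 0, "n_ns": 0}
    for statuses in status_by_target.values():
        if isinstance(statuses, str):
            statuses = [statuses]
        s = set(statuses) & {"up", "down"}
        if s == {"down"}:
            counts["n_down"] += 1
        elif s == {"up"}:
            counts["n_up"] += 1
        elif s == {"up", "down"}:
            counts["n_both"] += 1
        else:
            counts["n_ns"] += 1
    counts["total"] = sum(counts.values())
    return counts


def write_sif(g: nx.Graph, path, relation: str = "interacts") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for v in sorted(nx.isolates(g)):
            fh.write(f"{v}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
            elif len(parts) >= 3:
                g.add_edge(parts[0], parts[2])
    return g
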