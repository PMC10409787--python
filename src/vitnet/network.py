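"""Thresholded co-occurrence network construction and topology metrics.

The network retains positive correlations at or above a threshold (default
0.35) as undirected weighted edges. Topology is summarized by unnormalized
betweenness centrality

    b(v) = sum over unordered pairs s != t (both != v) of
           sigma(s, t | v) / sigma(s, t)

with unweighted shortest paths (correlation weights are similarities, not
lengths), by the density d = 2m / (n (n - 1)), and by a modularity-maximizing
partition (Louvain heuristics, cross-checked with Girvan-Newman).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from vitnet.io import CorrelationMatrix

logger = logging.getLogger("vitnet")


@dataclass
class CentralityTable:
    """Unnormalized betweenness per node, with the normalized value and the
    degree carried along for reporting and tie-breaking."""

    b: dict[str, float]
    b_normalized: dict[str, float]
    degree: dict[str, int]

    def top(self, k: int) -> list[str]:
        order = sorted(
            self.b, key=lambda v: (-self.b[v], -self.degree[v], str(v))
        )
        return order[:k]


@dataclass
class Partition:
    """Node -> module assignment with its modularity score."""

    assignment: dict[str, int]
    modularity: float
    method: str
    seed: int | None = None

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, []).append(node)
        return out


@dataclass
class NetworkSummary:
    n: int
    m: int
    d: float
    mean_degree: float
    Q: float | None = None
    n_modules: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n,
            "n_edges": self.m,
            "density": self.d,
            "mean_degree": self.mean_degree,
            "modularity": self.Q,
            "n_modules": self.n_modules,
        }


def build_network(
    corr: CorrelationMatrix,
    threshold: float = 0.35,
    positive_only: bool = True,
    p_max: float | None = None,
) -> nx.Graph:
    """Retain correlations >= threshold as weighted undirected edges.

    With ``positive_only`` (the default) only positive correlations are
    eligible; otherwise the threshold applies to |r|. Optional p-value
    filtering keeps an edge only when its permutation p <= ``p_max``.
    Nodes left without any retained edge are excluded (and logged).
    """
    if positive_only and threshold <= 0:
        raise ValueError("threshold must be positive when positive_only is set")
    if not (0 < abs(threshold) <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if p_max is not None and corr.p is None:
        raise ValueError("p_max given but the correlation matrix has no p-values")

    ids = corr.genome_ids
    r = corr.r
    g = nx.Graph()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            val = r[i, j]
            keep = val >= threshold if positive_only else abs(val) >= threshold
            if keep and p_max is not None:
                keep = corr.p[i, j] <= p_max
            if keep:
                g.add_edge(ids[i], ids[j], weight=float(val))
    dropped = n - g.number_of_nodes()
    if dropped:
        logger.info(
            "ISOLATED_NODES_DROPPED\t%d of %d genomes had no retained edge",
            dropped,
            n,
        )
    if g.number_of_nodes() == 0:
        logger.warning("EMPTY_NETWORK\tno correlation passed the threshold")
    return g


def betweenness(net: nx.Graph) -> CentralityTable:
    """Unnormalized betweenness centrality over unweighted shortest paths.

    Pairs in different components contribute zero; isolated nodes score 0.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot compute betweenness of an empty network")
    raw = nx.betweenness_centrality(net, normalized=False, weight=None)
    norm = nx.betweenness_centrality(net, normalized=True, weight=None)
    degree = dict(net.degree())
    return CentralityTable(
        {v: float(b) for v, b in raw.items()},
        {v: float(b) for v, b in norm.items()},
        degree,
    )


def density(net: nx.Graph) -> float:
    """Realized fraction of possible edges, d = 2m / (n (n - 1))."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def delineate_hubs(
    cent: CentralityTable,
    method: str = "top_k",
    k: int | None = None,
    sd_mult: float = 2.0,
) -> list[str]:
    """Pick hub nodes from the betweenness table.

    ``top_k`` takes the k highest-betweenness nodes (ties broken by higher
    degree, then lexicographic node id); ``mean_plus_sd`` takes nodes with
    b > mean(b) + sd_mult * sd(b). When k is omitted it defaults to
    max(1, round(0.07 n)), roughly the hub fraction of a 120-node network
    with 8 hubs.
    """
    if not cent.b:
        raise ValueError("empty centrality table")
    n = len(cent.b)
    if method == "top_k":
        if k is None:
            k = max(1, round(0.07 * n))
        if k > n:
            raise ValueError(f"k={k} exceeds node count {n}")
        return cent.top(k)
    if method == "mean_plus_sd":
        vals = np.array(list(cent.b.values()))
        cutoff = vals.mean() + sd_mult * vals.std(ddof=0)
        hubs = [v for v, b in cent.b.items() if b > cutoff]
        return sorted(hubs, key=lambda v: (-cent.b[v], -cent.degree[v], str(v)))
    raise ValueError(f"unknown hub method {method!r}")


def _partition_quality(net: nx.Graph, communities) -> float:
    if net.number_of_edges() == 0:
        return 0.0
    return nx.community.modularity(net, communities, weight="weight")


def detect_modules(net: nx.Graph, method: str = "louvain", seed: int = 0) -> Partition:
    """Partition the network into modules.

    Louvain greedily maximizes weighted modularity at resolution 1.0,
    deterministic under ``seed``. Girvan-Newman removes highest-betweenness
    edges and returns the partition along the removal hierarchy (including
    the trivial one-module partition) with maximal modularity.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    if net.number_of_edges() == 0:
        assignment = {v: i for i, v in enumerate(sorted(net.nodes, key=str))}
        return Partition(assignment, 0.0, method, seed)
    if method == "louvain":
        comms = nx.community.louvain_communities(
            net, weight="weight", resolution=1.0, seed=seed
        )
    elif method == "girvan_newman":
        candidates = [[set(net.nodes)]]
        if nx.number_connected_components(net) > 1:
            candidates.append(list(nx.connected_components(net)))
        for level in nx.community.girvan_newman(net):
            candidates.append([set(c) for c in level])
            if len(level) == net.number_of_nodes():
                break
        comms = max(candidates, key=lambda c: _partition_quality(net, c))
    else:
        raise ValueError(f"unknown module method {method!r}")
    q = _partition_quality(net, comms)
    # stable module ids: number modules by their lexicographically first member
    ordered = sorted(comms, key=lambda c: min(str(v) for v in c))
    assignment = {v: i for i, comm in enumerate(ordered) for v in comm}
    return Partition(assignment, float(q), method, seed)


def summarize(
    net: nx.Graph,
    cent: CentralityTable | None = None,
    part: Partition | None = None,
) -> NetworkSummary:
    """Headline topology statistics: n, m, density, mean degree, modularity."""
    n = net.number_of_nodes()
    m = net.number_of_edges()
    d = density(net) if n >= 2 else 0.0
    mean_degree = 2.0 * m / n if n else 0.0
    q = part.modularity if part is not None else None
    n_modules = part.n_modules if part is not None else None
    return NetworkSummary(n, m, d, mean_degree, q, n_modules)
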