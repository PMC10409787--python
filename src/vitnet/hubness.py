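"""The vitamin-hubness metric and its label-randomization null.

For a producer node v in the co-occurrence network the score is

    h(v) = D_total(v) * D_auxotroph(v) / [ (1/N) * sum_a P(a) ]

where D_total is v's degree, D_auxotroph the number of v's neighbors labeled
auxotroph, N = D_auxotroph that same neighbor count, and P(a) the number of
producer-labeled nodes adjacent to auxotrophic neighbor a (v itself counts,
so the mean producer-degree is >= 1 and h <= D_total * D_auxotroph). A
producer with no auxotrophic neighbors scores 0: it shows no provisioning
evidence. High h flags producers whose correlated auxotrophs have few
alternative producers.

Significance is assessed by relabeling: each simulation draws a uniform
random producer set of the observed size (by default with the focal node
forced into it), labels all other nodes auxotroph, and recomputes h(focal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from vitnet.pathways import RoleLabels

logger = logging.getLogger("vitnet")


@dataclass(frozen=True)
class HubnessScore:
    node: str
    D_total: int
    D_auxotroph: int
    N: int
    producer_links: tuple[int, ...]  # per auxotrophic neighbor, sorted by id
    denom: float
    h: float

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "D_total": self.D_total,
            "D_auxotroph": self.D_auxotroph,
            "N": self.N,
            "producer_links": list(self.producer_links),
            "denom": self.denom,
            "h": self.h,
        }


@dataclass
class NullDistribution:
    focal: str
    n_sim: int
    seed: int
    focal_policy: str
    scores: np.ndarray
    h_obs: float
    n_ill_defined: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != self.n_sim:
            raise ValueError("scores length disagrees with n_sim")

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1)) if self.n_sim > 1 else 0.0

    @property
    def z(self) -> float | None:
        sd = self.sd
        if sd == 0:
            return None
        return (self.h_obs - self.mean) / sd

    @property
    def empirical_p(self) -> float:
        return (1.0 + int((self.scores >= self.h_obs - 1e-12).sum())) / (
            1.0 + self.n_sim
        )

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "focal_policy": self.focal_policy,
            "h_obs": self.h_obs,
            "mean": self.mean,
            "sd": self.sd,
            "z": self.z,
            "empirical_p": self.empirical_p,
            "n_ill_defined": self.n_ill_defined,
        }


def _roles_mapping(labels: RoleLabels | Mapping[str, str]) -> Mapping[str, str]:
    return labels.roles if isinstance(labels, RoleLabels) else labels


def hub_score(
    net: nx.Graph, labels: RoleLabels | Mapping[str, str], v: str
) -> HubnessScore:
    """Evaluate the vitamin-hubness score of node v with all components.

    ``labels`` must cover every network node. The score is defined for any
    labeled node but is meaningful for producers (for which denom >= 1).
    """
    roles = _roles_mapping(labels)
    if v not in net:
        raise KeyError(f"node {v!r} not in network")
    if v not in roles:
        raise KeyError(f"node {v!r} has no role label")
    missing = set(net.nodes) - set(roles)
    if missing:
        raise KeyError(f"network nodes without role labels: {sorted(missing)[:5]}")
    neighbors = list(net[v])
    d_total = len(neighbors)
    aux = sorted((a for a in neighbors if roles[a] == "auxotroph"), key=str)
    n = len(aux)
    if n == 0:
        return HubnessScore(v, d_total, 0, 0, (), 0.0, 0.0)
    links = tuple(
        sum(1 for b in net[a] if roles[b] == "producer") for a in aux
    )
    denom = sum(links) / n
    h = 0.0 if denom == 0 else d_total * n / denom
    return HubnessScore(v, d_total, n, n, links, denom, h)


def rank_hub_scores(
    net: nx.Graph, labels: RoleLabels | Mapping[str, str]
) -> list[HubnessScore]:
    """Score every producer-labeled network node, descending by h.

    Ties break by higher auxotroph-neighbor count, then node id. Nodes not
    labeled producer are not scored (not-applicable, rather than 0).
    """
    roles = _roles_mapping(labels)
    producers = [v for v in net.nodes if roles.get(v) == "producer"]
    if not producers:
        logger.warning("NO_PRODUCERS\tno producer-labeled node in the network")
        return []
    scores = [hub_score(net, labels, v) for v in producers]
    return sorted(scores, key=lambda s: (-s.h, -s.D_auxotroph, str(s.node)))


def randomization_null(
    net: nx.Graph,
    labels: RoleLabels | Mapping[str, str],
    focal: str,
    n_sim: int = 1000,
    seed: int = 0,
    focal_policy: str = "focal_forced_producer",
) -> NullDistribution:
    """Producer-label randomization null for the focal node's score.

    Every simulation preserves the observed producer count. Under
    ``focal_forced_producer`` the focal node is always a producer and the
    remaining producers are drawn from the other nodes; under
    ``free_relabel`` all nodes are eligible and draws that label the focal
    node auxotroph are recorded as h = 0 and counted in ``n_ill_defined``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if focal_policy not in ("focal_forced_producer", "free_relabel"):
        raise ValueError(f"unknown focal_policy {focal_policy!r}")
    roles = _roles_mapping(labels)
    if focal not in net:
        raise KeyError(f"focal node {focal!r} not in network")
    h_obs = hub_score(net, labels, focal).h

    nodes = sorted(net.nodes, key=str)
    n_prod = sum(1 for v in nodes if roles.get(v) == "producer")
    if n_prod == 0:
        raise ValueError("no producers among network nodes")
    others = [v for v in nodes if v != focal]
    rng = np.random.default_rng(seed)
    scores = np.empty(n_sim)
    n_ill = 0
    for i in range(n_sim):
        if focal_policy == "focal_forced_producer":
            chosen = rng.choice(len(others), size=n_prod - 1, replace=False)
            producers = {focal} | {others[j] for j in chosen}
        else:
            chosen = rng.choice(len(nodes), size=n_prod, replace=False)
            producers = {nodes[j] for j in chosen}
            if focal not in producers:
                n_ill += 1
                scores[i] = 0.0
                continue
        sim_roles = {
            v: ("producer" if v in producers else "auxotroph") for v in nodes
        }
        scores[i] = hub_score(net, sim_roles, focal).h
    return NullDistribution(
        focal, n_sim, seed, focal_policy, scores, h_obs, n_ill
    )
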