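"""Leadership network assembly, node scores, and the vicinity cross-check.

Pairwise relations from the delay analysis become a mixed graph: directed
edges point leader -> follower, undirected edges mark evenly matched pairs,
unconnected pairs contribute no edge.  A node's *leading tendency* is the
number of individuals reachable along directed edges only (the leadership
rank); *active connections* counts incident edges of either kind.

An independent vicinity network — pairs that spend more time within a
radius of each other than a time-shift randomization null predicts — serves
as a cross-check that needs no synchronised movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .track_preprocess import Walk

__all__ = [
    "NetworkEdge",
    "LeadershipNetwork",
    "build_network",
    "leading_tendency",
    "active_connections",
    "node_scores",
    "vicinity_network",
    "network_agreement",
]


@dataclass(frozen=True)
class NetworkEdge:
    pair: tuple[str, str]
    directed: bool
    leader: str | None
    tau_mode: float
    leading_ratio: float


@dataclass
class LeadershipNetwork:
    nodes: list[str]
    edges: list[NetworkEdge] = field(default_factory=list)

    def directed_graph(self) -> nx.DiGraph:
        """Directed edges only, leader -> follower."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.directed:
                follower = e.pair[1] if e.leader == e.pair[0] else e.pair[0]
                g.add_edge(e.leader, follower, tau_mode=e.tau_mode,
                           leading_ratio=e.leading_ratio)
        return g

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e.pair, directed=e.directed, leader=e.leader,
                       tau_mode=e.tau_mode, leading_ratio=e.leading_ratio)
        return g

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"i": e.pair[0], "j": e.pair[1], "directed": e.directed,
                 "leader": e.leader, "tau_mode": e.tau_mode,
                 "leading_ratio": e.leading_ratio}
                for e in self.edges
            ]
        )


def build_network(relations, nodes: list[str] | None = None) -> LeadershipNetwork:
    """Assemble relations into a network; unconnected pairs leave no edge."""
    seen = set()
    all_nodes = list(nodes) if nodes is not None else []
    edges = []
    for rel in relations:
        key = frozenset(rel.pair)
        if key in seen:
            raise ValueError(f"duplicate pair {tuple(sorted(rel.pair))}")
        seen.add(key)
        for n in rel.pair:
            if n not in all_nodes:
                all_nodes.append(n)
        if rel.status == "unconnected":
            continue
        edges.append(NetworkEdge(rel.pair, rel.status == "directed", rel.leader,
                                 rel.tau_mode, rel.leading_ratio))
    return LeadershipNetwork(all_nodes, edges)


def leading_tendency(net: LeadershipNetwork, node: str) -> int:
    """Number of followers reachable through directed links (self excluded)."""
    if node not in net.nodes:
        raise KeyError(node)
    return len(nx.descendants(net.directed_graph(), node))


def active_connections(net: LeadershipNetwork, node: str) -> int:
    """Incident edges, directed or undirected."""
    if node not in net.nodes:
        raise KeyError(node)
    return sum(node in e.pair for e in net.edges)


def node_scores(net: LeadershipNetwork) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "leading_tendency": {n: leading_tendency(net, n) for n in net.nodes},
            "active_connections": {n: active_connections(net, n) for n in net.nodes},
        }
    ).rename_axis("node")


def vicinity_fraction(pos_a: np.ndarray, pos_b: np.ndarray, radius: float) -> float:
    return float(np.mean(np.linalg.norm(pos_a - pos_b, axis=1) <= radius))


def vicinity_network(walks: list[Walk], radius: float = 5.0, n_shifts: int = 100,
                     quantile: float = 0.95, seed: int = 0,
                     min_shift: float = 60.0) -> nx.Graph:
    """Undirected co-location network against a circular time-shift null.

    For each dog pair the observed statistic is the pooled fraction of grid
    time the two are within ``radius`` of each other.  The null circularly
    shifts one track per walk by a random offset of at least ``min_shift``
    seconds, preserving each track's marginal statistics; a pair is an edge
    when the observed fraction exceeds the ``quantile`` of the null draws.
    Walks shorter than twice ``min_shift`` are excluded with a warning.

    The per-pair observed and null-quantile values are attached as a table
    in ``graph.graph["pair_table"]``.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    usable = []
    for w in walks:
        if w.duration < 2 * min_shift:
            warnings.warn(f"walk {w.walk_id!r} shorter than twice the minimum "
                          "shift; excluded from the vicinity null")
        else:
            usable.append(w)
    if not usable:
        raise ValueError("no walk long enough for the vicinity null")
    dogs = sorted(usable[0].dog_ids)
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(dogs)
    rows = []
    for ai, a in enumerate(dogs):
        for b in dogs[ai + 1:]:
            n_tot = sum(w.n_samples for w in usable)
            obs = sum(
                vicinity_fraction(w.positions[a], w.positions[b], radius)
                * w.n_samples for w in usable) / n_tot
            null = np.empty(n_shifts)
            for k in range(n_shifts):
                acc = 0.0
                for w in usable:
                    lo = round(min_shift / w.dt)
                    off = int(rng.integers(lo, w.n_samples - lo + 1))
                    shifted = np.roll(w.positions[b], off, axis=0)
                    acc += vicinity_fraction(w.positions[a], shifted,
                                             radius) * w.n_samples
                null[k] = acc / n_tot
            thresh = float(np.quantile(null, quantile))
            if obs > thresh:
                g.add_edge(a, b, observed=obs, null_quantile=thresh)
            rows.append({"i": a, "j": b, "observed": obs,
                         "null_quantile": thresh, "edge": obs > thresh})
    g.graph["pair_table"] = pd.DataFrame(rows)
    return g


def network_agreement(values_a, values_b) -> tuple[float, float]:
    """Pearson correlation (with two-tailed p) between two per-pair scores."""
    from .association_stats import pearson_r, r_to_p

    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) != len(b):
        raise ValueError("pair score vectors differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    r = pearson_r(a, b)
    return r, r_to_p(r, len(a))
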