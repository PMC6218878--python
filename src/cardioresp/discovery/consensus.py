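"""Cross-method consensus over learned graphs."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from cardioresp.types import CausalGraph

__all__ = ["ConsensusReport", "consensus"]


@dataclass
class ConsensusReport:
    """Support per ordered pair and the well-supported paths.

    ``support[(a, b)]`` counts methods asserting a -> b; an undirected
    CPDAG edge contributes 0.5 to each direction.  ``paths`` holds node
    chains whose consecutive edges all meet the minimum support.
    """

    nodes: tuple
    support: dict = field(default_factory=dict)        # (a, b) -> float
    supporters: dict = field(default_factory=dict)     # (a, b) -> list[str]
    paths: list = field(default_factory=list)
    n_methods: int = 0
    min_support: float = 0.0

    def summary(self) -> str:
        lines = [f"Consensus over {self.n_methods} methods "
                 f"(min support {self.min_support:g}):"]
        for (a, b), s in sorted(self.support.items(), key=lambda kv: (-kv[1], kv[0])):
            who = ",".join(self.supporters[(a, b)])
            lines.append(f"  {a} -> {b}: {s:g}  [{who}]")
        if self.paths:
            lines.append("Paths:")
            for path in self.paths:
                lines.append("  " + " -> ".join(path))
        else:
            lines.append("Paths: none meet the support threshold")
        return "\n".join(lines)


def consensus(graphs: list[CausalGraph], min_support: float = 3.0) -> ConsensusReport:
    """Count per-direction support across graphs and extract supported paths."""
    if not graphs:
        raise ValueError("no graphs given")
    node_set = set(graphs[0].nodes)
    for g in graphs[1:]:
        if set(g.nodes) != node_set:
            raise ValueError("graphs must share an identical node set")

    support: dict = {}
    supporters: dict = {}

    def add(a, b, weight, method):
        support[(a, b)] = support.get((a, b), 0.0) + weight
        supporters.setdefault((a, b), []).append(method)

    for g in graphs:
        for a, b in g.directed_edges:
            add(a, b, 1.0, g.method)
        for a, b in g.undirected_edges:
            add(a, b, 0.5, g.method + "(und)")
            add(b, a, 0.5, g.method + "(und)")

    strong = nx.DiGraph()
    strong.add_nodes_from(node_set)
    strong.add_edges_from(e for e, s in support.items() if s >= min_support)

    # maximal simple paths of >= 2 edges through well-supported edges
    paths = []
    for src in sorted(strong.nodes):
        for dst in sorted(strong.nodes):
            if src == dst:
                continue
            for path in nx.all_simple_paths(strong, src, dst, cutoff=len(node_set)):
                if len(path) >= 3:
                    paths.append(tuple(path))
    maximal = [
        p for p in paths
        if not any(q != p and _is_subpath(p, q) for q in paths)
    ]
    return ConsensusReport(
        nodes=tuple(sorted(node_set)),
        support=support,
        supporters=supporters,
        paths=sorted(set(maximal)),
        n_methods=len(graphs),
        min_support=min_support,
    )


def _is_subpath(short, long):
    k = len(short)
    return any(tuple(long[i:i + k]) == tuple(short) for i in range(len(long) - k + 1))
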