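"""Enumeration of the full scaffold space as a reaction-adjacency graph.

Nodes are every scaffold code the grammar's valence table admits; an
undirected edge joins two codes whenever one registered reaction converts one
into the other (generalized distance exactly 1).  The iridoid preset yields
62,400 scaffolds; counting each adjacency in both directions — the
convention of a sparse adjacency matrix — gives 822,160 reactions, 411,080
of them unique undirected links.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass

import networkx as nx

from .codec import (
    DOUBLE_BOND,
    EPOXIDE,
    NO_FLAG,
    GrammarConfig,
    ScaffoldCode,
    format_code,
    iter_neighbor_codes,
)

__all__ = ["ChemSpace", "enumerate_space"]

UNREACHABLE = -1


@dataclass
class ChemSpace:
    """The enumerated scaffold space with integer-id adjacency."""

    config: GrammarConfig
    nodes: list[ScaffoldCode]
    index: dict[ScaffoldCode, int]
    adjacency: list[list[tuple[int, str]]]  # per node: (neighbor id, move kind)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Unique undirected reaction edges."""
        return sum(len(a) for a in self.adjacency) // 2

    def n_reactions(self, count_directions: bool = True) -> int:
        """Reaction count; by default each adjacency counts in both
        directions (the nonzero count of the sparse adjacency matrix)."""
        total = sum(len(a) for a in self.adjacency)
        return total if count_directions else total // 2

    def __contains__(self, code: ScaffoldCode) -> bool:
        return code in self.index

    def node_id(self, code: ScaffoldCode) -> int:
        try:
            return self.index[code]
        except KeyError:
            raise KeyError(
                f"scaffold {format_code(code)} is not in the space"
            ) from None

    def neighbors(self, code: ScaffoldCode) -> set[ScaffoldCode]:
        """Reaction-adjacent scaffolds (symmetric, never contains ``code``)."""
        i = self.node_id(code)
        return {self.nodes[j] for j, _ in self.adjacency[i]}

    def neighbor_ids(self, i: int) -> list[int]:
        return [j for j, _ in self.adjacency[i]]

    def geodesic(self, a: ScaffoldCode, b: ScaffoldCode) -> int:
        """Shortest-path reaction count; ``UNREACHABLE`` (-1) if separated."""
        src, dst = self.node_id(a), self.node_id(b)
        if src == dst:
            return 0
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v, _ in self.adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    if v == dst:
                        return dist[v]
                    q.append(v)
        return UNREACHABLE

    def bfs_ball(self, sources: list[int], radius: int) -> set[int]:
        """All node ids within ``radius`` reactions of any source."""
        seen = set(sources)
        frontier = list(seen)
        for _ in range(radius):
            nxt = []
            for u in frontier:
                for v, _ in self.adjacency[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
            if not frontier:
                break
        return seen

    def subgraph(self, node_ids: set[int]) -> nx.Graph:
        """Induced networkx subgraph with code keys as a node attribute."""
        g = nx.Graph()
        for i in node_ids:
            g.add_node(i, code=format_code(self.nodes[i]))
        for i in node_ids:
            for j, kind in self.adjacency[i]:
                if j in node_ids and i < j:
                    g.add_edge(i, j, kind=kind)
        return g

    def to_networkx(self) -> nx.Graph:
        return self.subgraph(set(range(self.n_nodes)))

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, path: str) -> None:
        """Compact TSV edge list of serialized codes plus the move kind."""
        with open(path, "w") as fh:
            fh.write("source\ttarget\tkind\n")
            for i in range(self.n_nodes):
                ki = format_code(self.nodes[i])
                for j, kind in self.adjacency[i]:
                    if i < j:
                        fh.write(f"{ki}\t{format_code(self.nodes[j])}\t{kind}\n")


def _labeled_flag_patterns(config: GrammarConfig):
    """Every way of placing disjoint double-bond/epoxide pairs on the
    skeleton: yields per-carbon flag tuples."""
    nb = len(config.bonds)
    eligible = sorted(config.double_bond_bonds | config.epoxide_bonds)
    patterns = []
    for r in range(len(eligible) + 1):
        for sub in itertools.combinations(eligible, r):
            verts: set[int] = set()
            ok = True
            for e in sub:
                a, b = config.bonds[e]
                if a in verts or b in verts:
                    ok = False
                    break
                verts.update((a, b))
            if not ok:
                continue
            label_opts = []
            for e in sub:
                labs = []
                if e in config.double_bond_bonds:
                    labs.append(DOUBLE_BOND)
                if e in config.epoxide_bonds:
                    labs.append(EPOXIDE)
                label_opts.append(labs)
            for labels in itertools.product(*label_opts):
                flags = [NO_FLAG] * config.n_carbons
                for e, lab in zip(sub, labels):
                    a, b = config.bonds[e]
                    flags[a] = lab
                    flags[b] = lab
                patterns.append(tuple(flags))
    return patterns


def enumerate_space(config: GrammarConfig) -> ChemSpace:
    """Exhaustively enumerate all valid codes and their reaction edges.

    Enumeration is deterministic: flag patterns in bond-subset order, then
    the per-carbon oxidation states in row-major order.
    """
    nodes: list[ScaffoldCode] = []
    index: dict[ScaffoldCode, int] = {}
    for flags in _labeled_flag_patterns(config):
        caps = []
        for i, f in enumerate(flags):
            if f == NO_FLAG:
                caps.append(config.max_real[i])
            else:
                caps.append(min(config.flag_cap(f), config.max_real[i]))
        for reals in itertools.product(*[range(c + 1) for c in caps]):
            code = ScaffoldCode(reals, flags)
            index[code] = len(nodes)
            nodes.append(code)
    if not nodes:
        raise ValueError("grammar admits no scaffolds")

    adjacency: list[list[tuple[int, str]]] = [[] for _ in nodes]
    for i, code in enumerate(nodes):
        for product, kind in iter_neighbor_codes(code, config):
            j = index.get(product)
            if j is None:
                raise AssertionError(
                    f"move {kind} left the enumerated space from "
                    f"{format_code(code)}"
                )
            adjacency[i].append((j, kind))
            adjacency[j].append((i, kind))
    return ChemSpace(config=config, nodes=nodes, index=index, adjacency=adjacency)
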