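"""Per-genus pathway hypotheses from sparse metabolite reports.

The *naïve prediction* for a genus places every reported scaffold in the
chemical space, extends it by ``n_reactions`` single-reaction steps, and
keeps every unit-distance link between included scaffolds.  Pruning then
enumerates candidate pathways — inclusion-minimal connected subgraphs that
join the reported scaffolds of each component — scores each by the
phylogenetic weight of its vertices and/or edges, and retains candidates
within ``tolerance`` percent of the best score.  The union of retained
candidates is the genus *pathway hypothesis*.  An ancestral pathway keeps
the items whose Felsenstein root weight across genus hypotheses exceeds a
threshold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from .chemspace import ChemSpace
from .codec import format_code, parse_code
from .phylo import (
    ItemScores,
    Phylogeny,
    ReportMatrix,
    score_items,
)

__all__ = [
    "ReconstructionParams",
    "PathwayHypothesis",
    "naive_predict",
    "edge_key",
    "build_item_matrix",
    "score_for_params",
    "prune_hypothesis",
    "reconstruct_genus",
    "reconstruct_all",
    "ancestral_pathway",
    "section5_preset",
]


@dataclass(frozen=True)
class ReconstructionParams:
    """The five user parameters of the reconstruction algorithm."""

    n_reactions: int = 0
    score_basis: str = "reported"  # reported | predicted
    scheme: str = "correlation"  # correlation | felsenstein
    apply_on: str = "vertices"  # vertices | edges | both
    tolerance: float = 10.0  # percent of the maximum score retained

    def __post_init__(self) -> None:
        if self.n_reactions < 0:
            raise ValueError("n_reactions must be >= 0")
        if self.score_basis not in ("reported", "predicted"):
            raise ValueError(f"bad score_basis {self.score_basis!r}")
        if self.scheme not in ("correlation", "felsenstein"):
            raise ValueError(f"bad scheme {self.scheme!r}")
        if self.apply_on not in ("vertices", "edges", "both"):
            raise ValueError(f"bad apply_on {self.apply_on!r}")
        if not 0 <= self.tolerance <= 100:
            raise ValueError("tolerance must be in [0, 100]")


@dataclass
class PathwayHypothesis:
    """A genus's phylogenetically pruned pathway.

    ``graph`` nodes are chemical-space ids with a ``status`` attribute
    (``reported`` in this genus, ``predicted`` = reported elsewhere in the
    family, ``theoretical`` = reported nowhere); edges are putative
    reactions.
    """

    genus: str
    graph: nx.Graph
    params: ReconstructionParams

    @property
    def reported_nodes(self) -> set[int]:
        return {
            n for n, d in self.graph.nodes(data=True)
            if d.get("status") == "reported"
        }

    @property
    def predicted_nodes(self) -> set[int]:
        return {
            n for n, d in self.graph.nodes(data=True)
            if d.get("status") != "reported"
        }


def _reported_ids(
    reports: ReportMatrix, space: ChemSpace, genus: str
) -> list[int]:
    row = reports.reported.loc[genus]
    ids = []
    for item in reports.items:
        if row[item]:
            code = parse_code(item, space.config)
            if code not in space:
                raise KeyError(
                    f"reported scaffold {item!r} (genus {genus}) is not in "
                    f"the chemical space"
                )
            ids.append(space.node_id(code))
    return sorted(set(ids))


def naive_predict(
    reports: ReportMatrix, space: ChemSpace, n_reactions: int
) -> dict[str, nx.Graph]:
    """Naïve prediction network per genus (no phylogeny involved).

    The scaffolds reported anywhere in the family are placed in the space
    together and extended by ``n_reactions``; unit-distance pairs are
    linked.  A genus's naïve prediction is the union of the connected
    components that contain at least one of *its own* reports, so a genus
    network can pass through scaffolds known only from other genera
    (status ``predicted``) or from nowhere (status ``theoretical``).
    """
    genus_seeds = {
        genus: set(_reported_ids(reports, space, genus))
        for genus in reports.genera
    }
    all_seeds = sorted(set().union(*genus_seeds.values())) if genus_seeds else []
    ball = space.bfs_ball(all_seeds, n_reactions) if all_seeds else set()
    family = space.subgraph(ball)
    family_reported = set().union(*genus_seeds.values()) if genus_seeds else set()
    comp_nodes = [sorted(c) for c in nx.connected_components(family)]
    comp_sets = [set(c) for c in comp_nodes]
    comp_edges = [list(family.subgraph(c).edges) for c in comp_nodes]
    out: dict[str, nx.Graph] = {}
    for genus in reports.genera:
        seeds = genus_seeds[genus]
        g = nx.Graph()
        for nodes, nodeset, edges in zip(comp_nodes, comp_sets, comp_edges):
            if not seeds & nodeset:
                continue
            for n in nodes:
                if n in seeds:
                    status = "reported"
                elif n in family_reported:
                    status = "predicted"
                else:
                    status = "theoretical"
                g.add_node(n, status=status)
            g.add_edges_from(edges)
        out[genus] = g
    return out


def edge_key(space: ChemSpace, u: int, v: int) -> str:
    """Canonical reaction-item key: endpoint code keys, sorted, '|'-joined."""
    a, b = format_code(space.nodes[u]), format_code(space.nodes[v])
    return f"{a}|{b}" if a <= b else f"{b}|{a}"


def build_item_matrix(
    reports: ReportMatrix,
    space: ChemSpace,
    naive: Mapping[str, nx.Graph],
    kind: str,
    basis: str,
) -> ReportMatrix:
    """Genus x item presence for scoring.

    kind "vertices": items are scaffold keys; reported = literature reports,
    predicted = membership of the genus's naïve graph.  kind "edges": items
    are reaction keys; a genus carries a reaction when both endpoint
    scaffolds have the corresponding presence (reported basis) or when the
    edge lies in its naïve graph (predicted basis).
    """
    genera = reports.genera
    pairs: list[tuple[str, str, str]] = []
    if kind == "vertices":
        for genus in genera:
            g = naive[genus]
            for n, d in g.nodes(data=True):
                key = format_code(space.nodes[n])
                pairs.append((genus, key, "predicted"))
                if d.get("status") == "reported":
                    pairs.append((genus, key, "reported"))
    elif kind == "edges":
        for genus in genera:
            g = naive[genus]
            for u, v in g.edges:
                key = edge_key(space, u, v)
                pairs.append((genus, key, "predicted"))
                if (
                    g.nodes[u].get("status") == "reported"
                    and g.nodes[v].get("status") == "reported"
                ):
                    pairs.append((genus, key, "reported"))
    else:
        raise ValueError(f"bad item kind {kind!r}")
    return ReportMatrix.from_pairs(pairs, genera=genera)


def score_for_params(
    reports: ReportMatrix,
    space: ChemSpace,
    tree: Phylogeny,
    naive: Mapping[str, nx.Graph],
    params: ReconstructionParams,
) -> dict[str, ItemScores]:
    """Item scores needed by ``params.apply_on`` (vertex and/or edge)."""
    out: dict[str, ItemScores] = {}
    kinds = {"vertices": ["vertices"], "edges": ["edges"],
             "both": ["vertices", "edges"]}[params.apply_on]
    for kind in kinds:
        m = build_item_matrix(reports, space, naive, kind, params.score_basis)
        out[kind] = score_items(
            m, tree, scheme=params.scheme, basis=params.score_basis
        )
    return out


def _item_score(
    scores: dict[str, ItemScores], kind: str, item: str, genus: str
) -> float:
    tab = scores[kind]
    if item not in tab.aggregate.index:
        return 0.0
    if tab.scheme == "correlation":
        return float(tab.per_genus.loc[genus, item])
    return float(tab.aggregate[item])


def _candidate_score(
    sub: nx.Graph,
    space: ChemSpace,
    scores: dict[str, ItemScores],
    params: ReconstructionParams,
    genus: str,
) -> float:
    total = 0.0
    if params.apply_on in ("vertices", "both"):
        for n in sub.nodes:
            total += _item_score(
                scores, "vertices", format_code(space.nodes[n]), genus
            )
    if params.apply_on in ("edges", "both"):
        for u, v in sub.edges:
            total += _item_score(scores, "edges", edge_key(space, u, v), genus)
    return total


def _minimal_connectors_exact(
    comp: nx.Graph, reported: set[int]
) -> list[set[int]]:
    """All inclusion-minimal node sets S >= reported with comp[S] connected."""
    optional = sorted(set(comp.nodes) - reported)
    found: list[set[int]] = []
    for r in range(len(optional) + 1):
        for extra in itertools.combinations(optional, r):
            s = reported | set(extra)
            if any(f < s for f in found):
                continue  # a subset already connects
            if nx.is_connected(comp.subgraph(s)):
                found.append(s)
    return found


def _peel_to_minimal_idx(adj, in_nodes, terminals_idx, n):
    """Minimal connector from a connected superset (integer-index form):
    BFS spanning tree, then peel non-terminal leaves."""
    start = terminals_idx[0]
    parent = [-2] * n  # -2 unvisited, -1 root
    parent[start] = -1
    order = [start]
    children = [[] for _ in range(n)]
    i = 0
    while i < len(order):
        u = order[i]
        i += 1
        for v in adj[u]:
            if in_nodes[v] and parent[v] == -2:
                parent[v] = u
                children[u].append(v)
                order.append(v)
    term = set(terminals_idx)
    deg = [0] * n
    alive = set(order)
    for u in order:
        deg[u] = len(children[u]) + (0 if parent[u] < 0 else 1)
    stack = [u for u in order if deg[u] <= 1 and u not in term]
    while stack:
        u = stack.pop()
        if u not in alive:
            continue
        alive.discard(u)
        nbs = children[u] + ([parent[u]] if parent[u] >= 0 else [])
        for v in nbs:
            if v in alive:
                deg[v] -= 1
                if deg[v] <= 1 and v not in term:
                    stack.append(v)
    return frozenset(alive)


def _connectors_sampled(
    comp: nx.Graph,
    reported: set[int],
    node_score: dict[int, float],
    cap: int,
    n_samples: int = 300,
    seed: int = 0,
) -> list[set[int]]:
    """Diverse minimal connectors by randomized shortest-path assembly.

    Each sample visits the reported nodes in a random order and joins the
    next one to the growing connector along a shortest path under jittered,
    score-discounted node weights, so high-scoring scaffolds are favored
    but alternative near-optimal routes are explored.  Each assembled
    subgraph is peeled to an inclusion-minimal connector; duplicates
    collapse.  The first sample is unjittered and terminal-ordered, giving
    a deterministic base connector.  Seeded and deterministic throughout.
    """
    import heapq

    import numpy as np

    terminals = sorted(reported)
    if len(terminals) == 1:
        return [set(terminals)]
    rng = np.random.default_rng(seed)
    nodes = list(comp.nodes)
    n = len(nodes)
    idx = {u: k for k, u in enumerate(nodes)}
    adj = [[idx[v] for v in comp.neighbors(u)] for u in nodes]
    terminals_idx = [idx[t] for t in terminals]
    smax = max(node_score.values()) if node_score else 1.0
    smax = smax if smax > 0 else 1.0
    base_w = np.array(
        [1.0 - 0.5 * node_score.get(u, 0.0) / smax for u in nodes]
    )
    seen: set[frozenset[int]] = set()
    out: list[set[int]] = []
    inf = float("inf")
    for k in range(n_samples + 1):
        if len(out) >= cap:
            break
        if k == 0:
            order = list(terminals_idx)
            w = base_w
        else:
            order = list(terminals_idx)
            rng.shuffle(order)
            w = base_w + 0.5 * rng.random(n)
        in_tree = [False] * n
        in_tree[order[0]] = True
        tree_list = [order[0]]
        ok = True
        for t in order[1:]:
            if in_tree[t]:
                continue
            dist = [inf] * n
            prev = [-1] * n
            dist[t] = 0.0
            heap = [(0.0, t)]
            hit = -1
            while heap:
                d, u = heapq.heappop(heap)
                if d > dist[u]:
                    continue
                if in_tree[u]:
                    hit = u
                    break
                for v in adj[u]:
                    nd = d + w[v]
                    if nd < dist[v]:
                        dist[v] = nd
                        prev[v] = u
                        heapq.heappush(heap, (nd, v))
            if hit < 0:
                ok = False
                break
            u = hit
            while u != t:
                if not in_tree[u]:
                    in_tree[u] = True
                    tree_list.append(u)
                u = prev[u]
            if not in_tree[t]:
                in_tree[t] = True
                tree_list.append(t)
        if not ok:
            continue
        cand = _peel_to_minimal_idx(adj, in_tree, terminals_idx, n)
        if cand not in seen:
            seen.add(cand)
            out.append({nodes[u] for u in cand})
    return out




def prune_hypothesis(
    genus: str,
    naive: nx.Graph,
    space: ChemSpace,
    scores: dict[str, ItemScores],
    params: ReconstructionParams,
    exact_cutoff: int = 15,
    candidate_cap: int = 10_000,
    candidate_samples: int = 300,
    seed: int = 0,
    connect: str = "genus",
) -> PathwayHypothesis:
    """Prune one genus's naïve graph into its pathway hypothesis.

    ``connect`` chooses the connector terminals: ``family`` joins every
    scaffold reported anywhere in the family (the genus's reported +
    predicted metabolites), ``genus`` joins only the genus's own reports.
    Components up to ``exact_cutoff`` nodes get exhaustive minimal-connector
    enumeration; larger ones use the seeded randomized assembly with
    ``candidate_samples`` draws, capped at ``candidate_cap`` candidates.
    """
    if connect not in ("family", "genus"):
        raise ValueError(f"bad connect {connect!r}")
    terminal_statuses = (
        {"reported"} if connect == "genus" else {"reported", "predicted"}
    )
    keep = nx.Graph()
    for comp_nodes in nx.connected_components(naive):
        comp = naive.subgraph(comp_nodes)
        reported = {
            n for n in comp.nodes
            if comp.nodes[n].get("status") in terminal_statuses
        }
        if not {
            n for n in comp.nodes if comp.nodes[n].get("status") == "reported"
        }:
            warnings.warn(
                f"{genus}: dropping a component of {len(comp_nodes)} nodes "
                f"with no reported scaffold"
            )
            continue
        if params.tolerance >= 100.0:
            chosen = comp
        else:
            if len(comp_nodes) <= exact_cutoff:
                connectors = _minimal_connectors_exact(comp, reported)
            else:
                node_score = {
                    n: _item_score(
                        scores, "vertices", format_code(space.nodes[n]), genus
                    ) if "vertices" in scores else 0.0
                    for n in comp.nodes
                }
                connectors = _connectors_sampled(
                    comp,
                    reported,
                    node_score,
                    candidate_cap,
                    n_samples=candidate_samples,
                    seed=seed,
                )
            scored = [
                (
                    _candidate_score(
                        comp.subgraph(s), space, scores, params, genus
                    ),
                    s,
                )
                for s in connectors
            ]
            best = max(sc for sc, _ in scored)
            cut = (1.0 - params.tolerance / 100.0) * best
            union_nodes: set[int] = set()
            union_edges: set[tuple[int, int]] = set()
            for sc, s in scored:
                if sc >= cut - 1e-12:
                    union_nodes |= s
                    # a reaction belongs to the hypothesis only when some
                    # retained candidate carries it
                    union_edges |= {
                        tuple(sorted(e)) for e in comp.subgraph(s).edges
                    }
            chosen = nx.Graph()
            chosen.add_nodes_from(union_nodes)
            chosen.add_edges_from(union_edges)
        for n in chosen.nodes:
            keep.add_node(n, **naive.nodes[n])
        keep.add_edges_from(chosen.edges(data=True))
    return PathwayHypothesis(genus=genus, graph=keep, params=params)


def reconstruct_genus(
    genus: str,
    reports: ReportMatrix,
    space: ChemSpace,
    tree: Phylogeny,
    params: ReconstructionParams,
    naive: Mapping[str, nx.Graph] | None = None,
    scores: dict[str, ItemScores] | None = None,
    **prune_kw,
) -> PathwayHypothesis:
    if naive is None:
        naive = naive_predict(reports, space, params.n_reactions)
    if scores is None:
        scores = score_for_params(reports, space, tree, naive, params)
    return prune_hypothesis(
        genus, naive[genus], space, scores, params, **prune_kw
    )


def reconstruct_all(
    reports: ReportMatrix,
    space: ChemSpace,
    tree: Phylogeny,
    params: ReconstructionParams,
    naive: Mapping[str, nx.Graph] | None = None,
    **prune_kw,
) -> dict[str, PathwayHypothesis]:
    """Pathway hypothesis for every genus of the report matrix."""
    if naive is None:
        naive = naive_predict(reports, space, params.n_reactions)
    scores = score_for_params(reports, space, tree, naive, params)
    return {
        genus: prune_hypothesis(
            genus, naive[genus], space, scores, params, **prune_kw
        )
        for genus in reports.genera
    }


def section5_preset(
    reports: ReportMatrix,
    space: ChemSpace,
    tree: Phylogeny,
    params0: ReconstructionParams | None = None,
    params1: ReconstructionParams | None = None,
    **prune_kw,
) -> dict[str, PathwayHypothesis]:
    """Two-stage protocol for natural data.

    The benchmark-selected 0-extension model runs first; the 1-extension
    model (with its own best parameters) is then applied only to reported
    scaffolds left without any connection, and only its components touching
    those scaffolds are merged in.  Scaffolds still unconnected stay as
    isolated reported nodes.
    """
    params0 = params0 or ReconstructionParams(
        0, "reported", "correlation", "vertices", 10.0
    )
    params1 = params1 or ReconstructionParams(
        1, "reported", "felsenstein", "vertices", 0.0
    )
    hyps = reconstruct_all(reports, space, tree, params0, **prune_kw)
    naive1 = None
    scores1 = None
    for genus, hyp in hyps.items():
        isolated = {
            n for n in hyp.reported_nodes if hyp.graph.degree(n) == 0
        }
        if not isolated:
            continue
        if naive1 is None:
            naive1 = naive_predict(reports, space, params1.n_reactions)
            scores1 = score_for_params(reports, space, tree, naive1, params1)
        hyp1 = prune_hypothesis(
            genus, naive1[genus], space, scores1, params1, **prune_kw
        )
        for comp in nx.connected_components(hyp1.graph):
            if comp & isolated and len(comp) > 1:
                sub = hyp1.graph.subgraph(comp)
                for n in sub.nodes:
                    if n not in hyp.graph:
                        hyp.graph.add_node(n, **sub.nodes[n])
                hyp.graph.add_edges_from(sub.edges(data=True))
    return hyps


def ancestral_pathway(
    hypotheses: Mapping[str, PathwayHypothesis],
    tree: Phylogeny,
    space: ChemSpace,
    threshold: float = 0.9,
    rate: float = 1.0,
) -> nx.Graph:
    """Items (nodes and reactions) whose root weight exceeds ``threshold``.

    Presence of an item in a genus means membership of that genus's pathway
    hypothesis; genera without the item are missing data under the pruning
    recursion, so unreported items are not penalized.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be inside (0, 1)")
    if len(hypotheses) < 2:
        raise ValueError("need hypotheses for at least 2 genera")
    from .phylo import felsenstein_root_weights_matrix

    genera = sorted(hypotheses)
    node_items = sorted({n for h in hypotheses.values() for n in h.graph.nodes})
    edge_items = sorted({
        tuple(sorted((u, v)))
        for h in hypotheses.values()
        for u, v in h.graph.edges
    })
    node_pres = pd.DataFrame(False, index=genera, columns=node_items)
    edge_pres = pd.DataFrame(
        False, index=genera, columns=range(len(edge_items))
    )
    for genus in genera:
        g = hypotheses[genus].graph
        for n in g.nodes:
            node_pres.loc[genus, n] = True
        present_edges = {tuple(sorted(e)) for e in g.edges}
        for k, e in enumerate(edge_items):
            if e in present_edges:
                edge_pres.loc[genus, k] = True
    node_w = felsenstein_root_weights_matrix(tree, node_pres, rate=rate)
    edge_w = felsenstein_root_weights_matrix(tree, edge_pres, rate=rate)
    out = nx.Graph()
    kept_nodes = set()
    for n in node_items:
        w = float(node_w[n])
        if w > threshold:
            out.add_node(n, code=format_code(space.nodes[n]), weight=w)
            kept_nodes.add(n)
    for k, (u, v) in enumerate(edge_items):
        w = float(edge_w[k])
        if w > threshold and u in kept_nodes and v in kept_nodes:
            out.add_edge(u, v, weight=w)
    return out
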