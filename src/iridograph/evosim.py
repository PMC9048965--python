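"""Neutral evolution of biosynthetic pathways along a phylogeny.

Three constraints shape the simulation: (i) novel catalytic activities
sample the reaction edges of the chemical space uniformly at random, and an
activity fixes only when at least one of its substrates is already
producible from the pathway entry point; (ii) an upper bound on enzyme
diversity — adding an enzyme beyond the cap evicts a uniformly chosen
existing one; (iii) a molecular clock — the number of exploration rounds on
a branch is proportional to its length.  Tips of the tree become genus
pathways; the ground truth (metabolites and enzymes per genus) is retained
for benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import networkx as nx
import numpy as np

from .chemspace import ChemSpace
from .codec import ScaffoldCode, format_code
from .phylo import Phylogeny, ReportMatrix

__all__ = [
    "EvolutionConfig",
    "SimulatedPathwaySet",
    "make_ancestral",
    "evolve",
    "sample_metabolites",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of one pathway-evolution run."""

    ancestral_edges: int = 10
    max_enzymes: int = 30
    rounds_per_unit: float = 5e4
    source_scaffold: ScaffoldCode | None = None  # None -> fully saturated
    seed: int = 0
    poisson_rounds: bool = False  # else round-half-up of rate x length

    def __post_init__(self) -> None:
        if self.ancestral_edges < 0 or self.max_enzymes <= 0:
            raise ValueError("ancestral_edges >= 0 and max_enzymes > 0 required")
        if self.ancestral_edges > self.max_enzymes:
            raise ValueError("ancestral_edges must be <= max_enzymes")
        if self.rounds_per_unit < 0:
            raise ValueError("rounds_per_unit must be >= 0")


@dataclass
class PathwayState:
    """Enzyme set (edges) plus the producible metabolite closure."""

    enzymes: set[tuple[int, int]]
    metabolites: set[int]

    def copy(self) -> "PathwayState":
        return PathwayState(set(self.enzymes), set(self.metabolites))


@dataclass
class SimulatedPathwaySet:
    """Evolved pathways at the tips plus internal-node snapshots."""

    config: EvolutionConfig
    source_id: int
    tip_states: dict[str, PathwayState]
    internal_states: dict[int, PathwayState]
    ancestral: PathwayState

    def tip_graph(self, space: ChemSpace, genus: str) -> nx.Graph:
        """Producible metabolites and the enzyme reactions among them."""
        state = self.tip_states[genus]
        g = nx.Graph()
        for n in state.metabolites:
            g.add_node(n, code=format_code(space.nodes[n]))
        for u, v in state.enzymes:
            if u in state.metabolites and v in state.metabolites:
                g.add_edge(u, v)
        return g

    def tip_graphs(self, space: ChemSpace) -> dict[str, nx.Graph]:
        return {g: self.tip_graph(space, g) for g in self.tip_states}


def _closure(
    source: int, enzymes: set[tuple[int, int]]
) -> set[int]:
    """Metabolites reachable from the source through the enzyme edges."""
    adj: dict[int, list[int]] = {}
    for u, v in enzymes:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    seen = {source}
    stack = [source]
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _space_edges(space: ChemSpace) -> list[tuple[int, int]]:
    edges = []
    for i in range(space.n_nodes):
        for j, _ in space.adjacency[i]:
            if i < j:
                edges.append((i, j))
    return edges


def make_ancestral(
    space: ChemSpace,
    config: EvolutionConfig,
    rng: np.random.Generator | None = None,
) -> PathwayState:
    """Grow a connected ancestral pathway of ``ancestral_edges`` reactions.

    Seeded random expansion: repeatedly pick a uniformly random space edge
    incident to the current producible set and add it.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    source = (
        space.node_id(config.source_scaffold)
        if config.source_scaffold is not None
        else space.node_id(ScaffoldCode.saturated(space.config))
    )
    state = PathwayState(set(), {source})
    for _ in range(config.ancestral_edges):
        frontier: list[tuple[int, int]] = []
        for u in state.metabolites:
            for v, _ in space.adjacency[u]:
                e = (u, v) if u < v else (v, u)
                if e not in state.enzymes:
                    frontier.append(e)
        frontier = sorted(set(frontier))
        if not frontier:
            raise ValueError(
                "ancestral_edges exceeds the reachable neighborhood"
            )
        e = frontier[rng.integers(len(frontier))]
        state.enzymes.add(e)
        state.metabolites = _closure(source, state.enzymes)
    return state


def _explore_branch(
    state: PathwayState,
    source: int,
    edges: list[tuple[int, int]],
    n_rounds: int,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> None:
    """Run exploration rounds in place on one branch."""
    draws = rng.integers(len(edges), size=n_rounds) if n_rounds else ()
    for idx in draws:
        e = edges[idx]
        u, v = e
        # fixation requires a substrate: an endpoint already producible
        if u not in state.metabolites and v not in state.metabolites:
            continue
        if e in state.enzymes:
            continue
        state.enzymes.add(e)
        if len(state.enzymes) > config.max_enzymes:
            victims = sorted(state.enzymes)
            out = victims[rng.integers(len(victims))]
            state.enzymes.discard(out)
        state.metabolites = _closure(source, state.enzymes)


def _n_rounds(
    length: float, config: EvolutionConfig, rng: np.random.Generator
) -> int:
    lam = config.rounds_per_unit * length
    if config.poisson_rounds:
        return int(rng.poisson(lam))
    return int(math.floor(lam + 0.5))  # round half-up


def evolve(
    space: ChemSpace,
    tree: Phylogeny,
    config: EvolutionConfig,
    ancestral: PathwayState | None = None,
) -> SimulatedPathwaySet:
    """Evolve pathways from the root to every tip of the tree.

    Pre-order traversal; each branch executes its clock-determined number of
    exploration rounds on an independent copy of the parent state.
    Reproducible for a fixed (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    if ancestral is None:
        ancestral = make_ancestral(space, config, rng)
    source = (
        space.node_id(config.source_scaffold)
        if config.source_scaffold is not None
        else space.node_id(ScaffoldCode.saturated(space.config))
    )
    edges = _space_edges(space)
    tip_states: dict[str, PathwayState] = {}
    internal_states: dict[int, PathwayState] = {}

    def walk(node, state: PathwayState) -> None:
        for child in node.child_nodes():
            child_state = state.copy()
            n_rounds = _n_rounds(child.edge.length or 0.0, config, rng)
            _explore_branch(child_state, source, edges, n_rounds, config, rng)
            if child.is_leaf():
                tip_states[child.taxon.label] = child_state
            else:
                internal_states[id(child)] = child_state
                walk(child, child_state)

    walk(tree.tree.seed_node, ancestral)
    return SimulatedPathwaySet(
        config=config,
        source_id=source,
        tip_states=tip_states,
        internal_states=internal_states,
        ancestral=ancestral,
    )


def save_simulation(
    sim: SimulatedPathwaySet, space: ChemSpace, outdir
) -> None:
    """Serialize a simulation as a directory: per-genus GraphML, a
    ground-truth CSV (genus, item, item kind) and the config as YAML."""
    import csv
    from pathlib import Path

    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genus in sorted(sim.tip_states):
        nx.write_graphml(
            sim.tip_graph(space, genus), outdir / f"{genus}.graphml"
        )
    with open(outdir / "ground_truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["genus", "item", "kind"])
        for genus in sorted(sim.tip_states):
            st = sim.tip_states[genus]
            for m in sorted(st.metabolites):
                w.writerow([genus, format_code(space.nodes[m]), "metabolite"])
            for u, v in sorted(st.enzymes):
                key = "|".join(
                    sorted((format_code(space.nodes[u]),
                            format_code(space.nodes[v])))
                )
                w.writerow([genus, key, "enzyme"])
    cfg = sim.config
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "ancestral_edges": cfg.ancestral_edges,
                "max_enzymes": cfg.max_enzymes,
                "rounds_per_unit": cfg.rounds_per_unit,
                "seed": cfg.seed,
                "poisson_rounds": cfg.poisson_rounds,
            },
            fh,
        )


def sample_metabolites(
    sim: SimulatedPathwaySet,
    space: ChemSpace,
    fraction: float,
    seed: int,
) -> ReportMatrix:
    """Report a uniform random subset of each genus's metabolites.

    ``ceil(fraction * n)`` metabolites per genus are marked reported; the
    simulation itself retains the ground truth for benchmarking.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str, str]] = []
    for genus in sorted(sim.tip_states):
        mets = sorted(sim.tip_states[genus].metabolites)
        if not mets:
            import warnings

            warnings.warn(f"genus {genus} has an empty pathway")
            continue
        k = math.ceil(fraction * len(mets))
        chosen = rng.choice(len(mets), size=k, replace=False)
        for idx in sorted(chosen):
            key = format_code(space.nodes[mets[idx]])
            pairs.append((genus, key, "reported"))
    return ReportMatrix.from_pairs(pairs, genera=sorted(sim.tip_states))
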