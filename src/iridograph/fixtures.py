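"""Synthetic fixtures: random trees, simulated reports, spiked expression.

Everything a full pipeline run needs can be generated from a seed, so the
package is testable end to end without any external download.  The defaults
mirror the study conditions: ~21 genera, pathway evolution under the
neutral exploration model, report sampling at 10–60%, and a tissue
expression matrix containing one genuinely coexpressed module around the
bait genes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .chemspace import ChemSpace
from .coexpression import ExpressionMatrix
from .evosim import EvolutionConfig, SimulatedPathwaySet, evolve, sample_metabolites
from .phylo import Phylogeny, ReportMatrix

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "random_phylogeny",
    "spiked_expression",
    "generate_fixture",
    "SAMPLING_FRACTIONS",
]

# benchmark preset: report sampling fractions, 10-60% in 10% steps
SAMPLING_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def random_phylogeny(
    n_tips: int = 21,
    seed: int = 0,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    ultrametric: bool = True,
    depth: float = 1.0,
) -> Phylogeny:
    """Seeded birth-death tree with tips G01..Gnn, scaled to unit depth.

    With ``ultrametric=False`` the branch lengths are jittered by +-50% so
    tip depths vary, as in a substitution-rate tree.
    """
    rng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # scale to the requested depth
    max_depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    if max_depth > 0:
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= depth / max_depth
    if not ultrametric:
        jitter = random.Random(seed + 1)
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 0.5 + jitter.random()
    for i, leaf in enumerate(
        sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label), start=1
    ):
        leaf.taxon.label = f"G{i:02d}"
    return Phylogeny(tree)


def spiked_expression(
    n_transcripts: int = 400,
    n_tissues: int = 8,
    module_size: int = 20,
    n_baits: int = 5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Expression matrix with one coexpressed module around the baits.

    Background transcripts get independent lognormal profiles; the module
    shares one tissue profile plus Gaussian noise on the log scale.
    Returns (matrix, module transcript ids, bait ids — the first
    ``n_baits`` module members).
    """
    if module_size > n_transcripts or n_baits > module_size:
        raise ValueError("module/bait sizes inconsistent")
    rng = np.random.default_rng(seed)
    tissues = [f"T{j + 1}" for j in range(n_tissues)]
    ids = [f"tr{i + 1:05d}" for i in range(n_transcripts)]
    log_bg = rng.normal(3.0, 1.5, size=(n_transcripts, n_tissues))
    profile = rng.normal(3.0, 2.0, size=n_tissues)
    module_ids = ids[:module_size]
    log_bg[:module_size] = profile + rng.normal(
        0.0, noise_sd, size=(module_size, n_tissues)
    )
    fpkm = np.maximum(2.0**log_bg - 1.0, 0.0)
    mat = ExpressionMatrix(pd.DataFrame(fpkm, index=ids, columns=tissues))
    return mat, module_ids, module_ids[:n_baits]


@dataclass(frozen=True)
class FixtureConfig:
    n_tips: int = 12
    ultrametric: bool = True
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    sampling_fraction: float = 0.5
    n_transcripts: int = 400
    n_tissues: int = 8
    module_size: int = 20
    n_baits: int = 5


@dataclass
class FixtureBundle:
    """One reproducible end-to-end test world."""

    config: FixtureConfig
    seed: int
    tree: Phylogeny
    simulation: SimulatedPathwaySet
    reports: ReportMatrix
    expression: ExpressionMatrix
    module_ids: list[str]
    baits: list[str]

    @property
    def provenance(self) -> dict:
        return {"seed": self.seed, "config": repr(self.config)}


def generate_fixture(
    space: ChemSpace, config: FixtureConfig | None = None, seed: int = 0
) -> FixtureBundle:
    """Deterministic bundle: tree, evolved pathways, sampled reports,
    spiked expression."""
    config = config or FixtureConfig()
    tree = random_phylogeny(
        n_tips=config.n_tips, seed=seed, ultrametric=config.ultrametric
    )
    evo = EvolutionConfig(
        ancestral_edges=config.evolution.ancestral_edges,
        max_enzymes=config.evolution.max_enzymes,
        rounds_per_unit=config.evolution.rounds_per_unit,
        source_scaffold=config.evolution.source_scaffold,
        seed=seed + 1,
        poisson_rounds=config.evolution.poisson_rounds,
    )
    sim = evolve(space, tree, evo)
    reports = sample_metabolites(
        sim, space, config.sampling_fraction, seed + 2
    )
    expr, module_ids, baits = spiked_expression(
        n_transcripts=config.n_transcripts,
        n_tissues=config.n_tissues,
        module_size=config.module_size,
        n_baits=config.n_baits,
        seed=seed + 3,
    )
    return FixtureBundle(
        config=config,
        seed=seed,
        tree=tree,
        simulation=sim,
        reports=reports,
        expression=expr,
        module_ids=module_ids,
        baits=baits,
    )
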