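"""Scaled replication of the surrogate-selection + parameter benchmark.

One seeded pipeline: simulate replicate pathway evolutions along a 21-genus
tree, sample each at the 10–60% report fractions, select the simulation
sets whose naïve-model topology most resembles a reference ("natural")
naïve model via the UMAP/Mahalanobis gate, then evaluate the three
benchmark-selected reconstruction presets on the selected surrogates and
pool confusion metrics.  Problem sizes default to a desk-scale run
(~20 replicate evolutions, 3 resamples per surrogate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemspace import ChemSpace
from .evosim import EvolutionConfig, evolve, sample_metabolites
from .fixtures import SAMPLING_FRACTIONS, random_phylogeny
from .optimize import TABLE_PRESETS, run_benchmark
from .phylo import Phylogeny
from .reconstruct import naive_predict
from .surrogates import (
    build_feature_table,
    embed_and_select,
    network_descriptors,
    transform_row_like,
)

__all__ = ["ScaledBenchmarkResult", "scaled_benchmark"]


@dataclass
class ScaledBenchmarkResult:
    tree: Phylogeny
    n_candidates: int
    selected: list[str]
    used: list[str]
    table: pd.DataFrame
    medians: dict[tuple[int, str], float]  # (extension, scope) -> median MCC
    quartiles: dict[tuple[int, str], tuple[float, float]]

    def median_mcc(self, extension: int, scope: str) -> float:
        return self.medians[(extension, scope)]


def _naive_descriptor_row(space, reports, genera):
    graphs = naive_predict(reports, space, 0)
    return np.concatenate(
        [network_descriptors(graphs[g]) for g in genera]
    )


@dataclass
class SurrogateSelection:
    tree: Phylogeny
    sims: dict
    selected: list[str]
    mahalanobis_sq: dict[str, float]
    n_candidates: int


def select_surrogates(
    space: ChemSpace,
    seed: int = 1,
    n_replicates: int = 50,
    n_tips: int = 21,
    fractions: tuple[float, ...] = SAMPLING_FRACTIONS,
    natural_fraction: float = 0.3,
    n_projections: int = 100,
    chi2_quantile: float = 0.99,
    evolution: EvolutionConfig | None = None,
) -> SurrogateSelection:
    """Simulate surrogate candidates and gate them against a reference.

    The reference naïve model comes from an extra, independent simulation
    sampled at ``natural_fraction``; every candidate is one replicate
    evolution sampled at one report fraction.
    """
    seed = int(seed) % (2**31 - 1)
    tree = random_phylogeny(n_tips=n_tips, seed=seed)
    genera = tree.tips
    base = evolution or EvolutionConfig()

    def evo_cfg(s):
        return EvolutionConfig(
            ancestral_edges=base.ancestral_edges,
            max_enzymes=base.max_enzymes,
            rounds_per_unit=base.rounds_per_unit,
            source_scaffold=base.source_scaffold,
            seed=s,
            poisson_rounds=base.poisson_rounds,
        )

    nat_sim = evolve(space, tree, evo_cfg(seed + 10_000))
    nat_reports = sample_metabolites(
        nat_sim, space, natural_fraction, seed + 20_000
    )
    nat_raw = _naive_descriptor_row(space, nat_reports, genera)

    sims = {}
    rows, ids = [], []
    for rep in range(n_replicates):
        sim = evolve(space, tree, evo_cfg(seed + rep))
        for fr in fractions:
            sid = f"r{rep:02d}f{int(round(fr * 100)):02d}"
            sims[sid] = (sim, fr)
            reports = sample_metabolites(
                sim, space, fr, seed + 1000 + rep * 100 + int(round(fr * 10))
            )
            graphs = naive_predict(reports, space, 0)
            rows.append({g: graphs[g] for g in genera})
            ids.append(sid)

    table = build_feature_table(rows, genera, set_ids=ids)
    nat_row = transform_row_like(table, nat_raw)
    selected, diag = embed_and_select(
        table,
        nat_row,
        n_projections=n_projections,
        chi2_quantile=chi2_quantile,
        seed=seed,
    )
    md2 = dict(zip(table.index, diag["mahalanobis_sq"]))
    return SurrogateSelection(
        tree=tree,
        sims=sims,
        selected=list(selected),
        mahalanobis_sq=md2,
        n_candidates=len(ids),
    )


def scaled_benchmark(
    space: ChemSpace,
    seed: int = 1,
    n_replicates: int = 50,
    n_tips: int = 21,
    fractions: tuple[float, ...] = SAMPLING_FRACTIONS,
    natural_fraction: float = 0.3,
    resamples: int = 3,
    n_projections: int = 100,
    chi2_quantile: float = 0.99,
    max_surrogates: int = 20,
    evolution: EvolutionConfig | None = None,
) -> ScaledBenchmarkResult:
    """Run the full selection + benchmark pipeline at reduced scale.

    Surrogates are ranked by Mahalanobis distance in the embedding; the
    χ²-selected sets enter first and, when the gate passes fewer than
    ``max_surrogates``, the next nature-closest candidates top the pool up
    deterministically.  Each surrogate is resampled ``resamples`` times at
    its own fraction.
    """
    sel = select_surrogates(
        space,
        seed=seed,
        n_replicates=n_replicates,
        n_tips=n_tips,
        fractions=fractions,
        natural_fraction=natural_fraction,
        n_projections=n_projections,
        chi2_quantile=chi2_quantile,
        evolution=evolution,
    )
    seed = int(seed) % (2**31 - 1)
    tree = sel.tree
    md2 = sel.mahalanobis_sq
    used = sorted(sel.selected, key=lambda s: md2[s])[:max_surrogates]
    if len(used) < max_surrogates:
        rest = sorted(
            (s for s in md2 if s not in set(used)),
            key=lambda s: md2[s],
        )
        used = used + rest[: max_surrogates - len(used)]
    sel_sims = {sid: sel.sims[sid] for sid in used}

    grid = [TABLE_PRESETS[0], TABLE_PRESETS[1], TABLE_PRESETS[2]]
    frames = []
    for params in grid:
        # tolerance-0 presets keep only top candidates; fewer samples suffice
        samples = 200 if params.tolerance > 0 else 24
        tab, _ = run_benchmark(
            sel_sims,
            space,
            tree,
            [params],
            resamples=resamples,
            seed=seed + 5000 + params.n_reactions,
            prune_kw={"candidate_samples": samples},
        )
        frames.append(tab)
    table_all = pd.concat(frames, ignore_index=True)

    medians = {}
    quartiles = {}
    for ext in (0, 1, 2):
        for scope in ("metabolites", "enzymes"):
            sub = table_all[
                (table_all.n_reactions == ext) & (table_all.scope == scope)
            ]["MCC"]
            medians[(ext, scope)] = float(sub.median())
            quartiles[(ext, scope)] = (
                float(sub.quantile(0.25)),
                float(sub.quantile(0.75)),
            )
    return ScaledBenchmarkResult(
        tree=tree,
        n_candidates=sel.n_candidates,
        selected=list(sel.selected),
        used=used,
        table=table_all,
        medians=medians,
        quartiles=quartiles,
    )
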