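"""Parameter-grid benchmarking of the reconstruction algorithm.

The grid crosses metabolite extension {0, 1, 2}, tolerance 0–100% in 10%
steps, weighting scheme {phylogenetic correlation, Felsenstein root
weights}, weight target {vertices, edges, both} and score basis {reported,
predicted}: 396 combinations.  Each combination is evaluated on surrogate
simulations by resampling their reports at the surrogate's sampling
fraction, reconstructing, and comparing prediction to ground truth with
confusion metrics on metabolites (nodes) and enzymes (edges); the
Matthews correlation coefficient selects the winning combination per
extension level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .chemspace import ChemSpace
from .evosim import SimulatedPathwaySet, sample_metabolites
from .phylo import Phylogeny
from .reconstruct import (
    PathwayHypothesis,
    ReconstructionParams,
    reconstruct_all,
)

__all__ = [
    "ConfusionMetrics",
    "parameter_grid",
    "confusion_metrics",
    "run_benchmark",
    "TABLE_PRESETS",
]

# the benchmark-selected rows of the published comparison tables
TABLE_PRESETS = {
    0: ReconstructionParams(0, "reported", "correlation", "vertices", 10.0),
    1: ReconstructionParams(1, "reported", "felsenstein", "vertices", 0.0),
    2: ReconstructionParams(2, "reported", "felsenstein", "vertices", 0.0),
}


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary confusion counts and rates for one scope."""

    scope: str  # metabolites | enzymes
    tp: int
    fp: int
    fn: int
    tn: int
    mcc_undefined: bool = False

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def false_omission_rate(self) -> float:
        return self.fn / (self.fn + self.tn) if (self.fn + self.tn) else 0.0

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def mcc(self) -> float:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        if fp == 0 and fn == 0 and tp > 0:
            return 1.0  # perfect agreement, even with no negatives in play
        denom = math.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        if denom == 0.0:
            return 0.0
        return (tp * tn - fp * fn) / denom

    @property
    def is_mcc_defined(self) -> bool:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        return math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)) > 0


def parameter_grid(
    extensions: Sequence[int] = (0, 1, 2),
    tolerances: Sequence[float] = tuple(range(0, 101, 10)),
    schemes: Sequence[str] = ("correlation", "felsenstein"),
    apply_on: Sequence[str] = ("vertices", "edges", "both"),
    bases: Sequence[str] = ("reported", "predicted"),
) -> list[ReconstructionParams]:
    """The full, deterministically ordered parameter grid (396 by default)."""
    grid = []
    for n in extensions:
        for basis in bases:
            for scheme in schemes:
                for on in apply_on:
                    for tol in tolerances:
                        grid.append(
                            ReconstructionParams(n, basis, scheme, on, tol)
                        )
    return grid


def confusion_metrics(
    predicted: nx.Graph,
    truth: nx.Graph,
    universe: tuple[set[int], set[tuple[int, int]]] | None = None,
    restrict_truth: bool = False,
) -> dict[str, ConfusionMetrics]:
    """Node (metabolite) and edge (enzyme) confusion against ground truth.

    The true-negative universe defaults to the union of both graphs — the
    caller normally passes the naïve-prediction universe so that negatives
    mean "considered but not chosen" rather than the whole chemical space.
    With ``restrict_truth`` the positives are likewise limited to the truth
    items inside the universe: scaffolds that no report ever placed in the
    solution space cannot be counted as misses of the pruning step.
    """
    if truth.number_of_nodes() == 0:
        raise ValueError("empty truth graph")
    pred_nodes = set(predicted.nodes)
    true_nodes = set(truth.nodes)
    pred_edges = {tuple(sorted(e)) for e in predicted.edges}
    true_edges = {tuple(sorted(e)) for e in truth.edges}
    if universe is None:
        u_nodes = pred_nodes | true_nodes
        u_edges = pred_edges | true_edges
    else:
        u_nodes = set(universe[0]) | pred_nodes
        u_edges = {tuple(sorted(e)) for e in universe[1]} | pred_edges
        if restrict_truth:
            true_nodes &= u_nodes
            true_edges &= u_edges
            if not true_nodes:
                raise ValueError("truth graph lies outside the universe")
        u_nodes |= true_nodes
        u_edges |= true_edges
    out = {}
    for scope, pr, tr, un in (
        ("metabolites", pred_nodes, true_nodes, u_nodes),
        ("enzymes", pred_edges, true_edges, u_edges),
    ):
        tp = len(pr & tr)
        fp = len(pr - tr)
        fn = len(tr - pr)
        tn = len(un - pr - tr)
        m = ConfusionMetrics(scope=scope, tp=tp, fp=fp, fn=fn, tn=tn)
        out[scope] = ConfusionMetrics(
            scope=scope, tp=tp, fp=fp, fn=fn, tn=tn,
            mcc_undefined=not m.is_mcc_defined,
        )
    return out


def _evaluate_once(
    sim: SimulatedPathwaySet,
    space: ChemSpace,
    tree: Phylogeny,
    params: ReconstructionParams,
    fraction: float,
    seed: int,
    prune_kw: dict,
    restrict_truth: bool = True,
) -> list[dict]:
    """Reconstruct one resampled surrogate and score every genus.

    Evaluation universe: the genus's naïve prediction (the solution space
    actually searched); by default the truth is restricted to that universe,
    so scaffolds no report ever placed in the space do not count as misses.
    """
    from .reconstruct import naive_predict

    reports = sample_metabolites(sim, space, fraction, seed)
    naive = naive_predict(reports, space, params.n_reactions)
    hyps = reconstruct_all(reports, space, tree, params, naive=naive, **prune_kw)
    truth_graphs = sim.tip_graphs(space)
    rows = []
    for genus, hyp in hyps.items():
        truth = truth_graphs[genus]
        if truth.number_of_nodes() == 0:
            continue
        uni_nodes = set(naive[genus].nodes)
        uni_edges = {tuple(sorted(e)) for e in naive[genus].edges}
        if not set(truth.nodes) & uni_nodes:
            continue
        mets = confusion_metrics(
            hyp.graph, truth, (uni_nodes, uni_edges),
            restrict_truth=restrict_truth,
        )
        for scope, m in mets.items():
            rows.append(
                {
                    "genus": genus,
                    "scope": scope,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "tn": m.tn,
                    "TPR": m.tpr,
                    "FPR": m.fpr,
                    "FOR": m.false_omission_rate,
                    "PPV": m.ppv,
                    "MCC": m.mcc,
                }
            )
    return rows


def run_benchmark(
    sims: Mapping[str, tuple[SimulatedPathwaySet, float]],
    space: ChemSpace,
    tree: Phylogeny,
    grid: Sequence[ReconstructionParams],
    resamples: int = 10,
    seed: int = 0,
    prune_kw: dict | None = None,
) -> tuple[pd.DataFrame, dict[int, ReconstructionParams]]:
    """Evaluate every grid combination on every surrogate.

    ``sims`` maps surrogate id -> (simulation, sampling fraction).  Each
    (combination, surrogate) cell is resampled ``resamples`` times at the
    surrogate's fraction.  Returns the pooled per-genus metrics table and
    the median-MCC-best combination per extension level (metabolite scope).
    """
    prune_kw = prune_kw or {}
    rng = np.random.default_rng(seed)
    records = []
    for gi, params in enumerate(grid):
        for sid, (sim, fraction) in sims.items():
            for rep in range(resamples):
                sub_seed = int(rng.integers(2**31 - 1))
                rows = _evaluate_once(
                    sim, space, tree, params, fraction, sub_seed, prune_kw
                )
                for r in rows:
                    r.update(
                        {
                            "grid_index": gi,
                            "surrogate": sid,
                            "resample": rep,
                            "n_reactions": params.n_reactions,
                            "score_basis": params.score_basis,
                            "scheme": params.scheme,
                            "apply_on": params.apply_on,
                            "tolerance": params.tolerance,
                        }
                    )
                    records.append(r)
    table = pd.DataFrame.from_records(records)
    best: dict[int, ReconstructionParams] = {}
    for ext in sorted({p.n_reactions for p in grid}):
        sub = table[(table.n_reactions == ext) & (table.scope == "metabolites")]
        med = sub.groupby("grid_index")["MCC"].median()
        best[ext] = grid[int(med.idxmax())]
    return table, best


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles per combination and scope, pooled over
    surrogate x resample x genus."""
    g = table.groupby(
        ["n_reactions", "score_basis", "scheme", "apply_on", "tolerance", "scope"]
    )
    q = g[["TPR", "FPR", "FOR", "PPV", "MCC"]].quantile([0.25, 0.5, 0.75])
    return q.unstack(level=-1)
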