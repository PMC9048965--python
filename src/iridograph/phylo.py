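"""Phylogenetic weighting of metabolite and reaction reports.

Two weighting schemes turn a binary genus x item report matrix into per-item
scores:

* **Phylogenetic correlation** — the tip-tip correlation implied by a
  Brownian-motion covariance on the rooted tree:
  ``corr(i, j) = t_shared / sqrt(depth_i * depth_j)`` where ``t_shared`` is
  the root-to-MRCA path length.  Scores are the report matrix times this
  correlation matrix.
* **Felsenstein root weights** — the posterior probability of the "present"
  state at the root under a symmetric two-state continuous-time model,
  computed with the pruning recursion.  Genera without a report are treated
  as *missing data* (partial likelihood 1 for both states), never as absent,
  so unreported molecules are not scored negatively.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from math import exp
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "ReportMatrix",
    "ItemScores",
    "phylo_correlation",
    "felsenstein_root_weight",
    "score_items",
]


class Phylogeny:
    """A rooted genus tree with branch lengths, backed by dendropy."""

    def __init__(self, tree: dendropy.Tree):
        if tree.seed_node is None or len(tree.seed_node.child_nodes()) < 2:
            raise ValueError("tree must be rooted with >= 2 root children")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None or edge.length < 0:
                raise ValueError(
                    "every non-root branch needs a nonnegative length"
                )
        self.tree = tree

    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Read a rooted newick tree from a path or a newick string."""
        if source.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out


@dataclass
class ReportMatrix:
    """Binary genus x item matrix with a reported/predicted status per cell.

    ``reported`` and ``predicted`` are boolean DataFrames over identical
    genus rows and item columns; predicted is a superset role (an item may be
    both).  Items are chemical-space node keys or reaction-edge keys.
    """

    reported: pd.DataFrame
    predicted: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.reported.index.equals(self.predicted.index) or not (
            self.reported.columns.equals(self.predicted.columns)
        ):
            raise ValueError("reported/predicted must share genera and items")
        self.reported = self.reported.astype(bool)
        self.predicted = self.predicted.astype(bool)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str, str]],
        genera: Iterable[str] | None = None,
    ) -> "ReportMatrix":
        """Build from (genus, item, status) triples, status in
        {reported, predicted}."""
        rows = list(pairs)
        for g, item, status in rows:
            if status not in ("reported", "predicted"):
                raise ValueError(f"bad status {status!r} for ({g}, {item})")
        genera = sorted(
            set(g for g, _, _ in rows) | set(genera or [])
        )
        items = sorted(set(i for _, i, _ in rows))
        gi = {g: k for k, g in enumerate(genera)}
        ii = {i: k for k, i in enumerate(items)}
        rep = np.zeros((len(genera), len(items)), dtype=bool)
        pred = np.zeros((len(genera), len(items)), dtype=bool)
        for g, item, status in rows:
            r, c = gi[g], ii[item]
            if status == "reported":
                rep[r, c] = True
            pred[r, c] = True
        return cls(
            pd.DataFrame(rep, index=genera, columns=items),
            pd.DataFrame(pred, index=genera, columns=items),
        )

    @property
    def genera(self) -> list[str]:
        return list(self.reported.index)

    @property
    def items(self) -> list[str]:
        return list(self.reported.columns)

    def basis(self, which: str) -> pd.DataFrame:
        if which == "reported":
            return self.reported
        if which == "predicted":
            return self.predicted
        raise ValueError(f"unknown basis {which!r}")


@dataclass
class ItemScores:
    """Per-item scores: a genus x item score table plus an aggregate row."""

    per_genus: pd.DataFrame
    aggregate: pd.Series
    scheme: str
    basis: str

    def item_score(self, item: str, genus: str | None = None) -> float:
        if genus is None:
            return float(self.aggregate[item])
        return float(self.per_genus.loc[genus, item])


def phylo_correlation(tree: Phylogeny, genera: list[str] | None = None) -> pd.DataFrame:
    """Brownian-motion tip correlation matrix (unit diagonal, in [0, 1])."""
    taxa = genera if genera is not None else tree.tips
    depths = tree.depths()
    for t in taxa:
        if t not in depths:
            raise KeyError(f"genus {t!r} missing from tree")
        if depths[t] <= 0:
            raise ValueError(f"tip {t!r} has zero depth")
    pdm = tree.tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(taxa)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            # shared path = (d_i + d_j - patristic distance)/2
            dij = pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]])
            shared = max(0.0, (depths[taxa[i]] + depths[taxa[j]] - dij) / 2.0)
            c = shared / np.sqrt(depths[taxa[i]] * depths[taxa[j]])
            corr[i, j] = corr[j, i] = c
    return pd.DataFrame(corr, index=taxa, columns=taxa)


def _transition(t: float, rate: float) -> tuple[float, float]:
    """(P(same), P(different)) for the symmetric 2-state model over time t."""
    e = exp(-2.0 * rate * t)
    return (1.0 + e) / 2.0, (1.0 - e) / 2.0


def felsenstein_root_weight(
    tree: Phylogeny,
    presence: Mapping[str, bool],
    rate: float = 1.0,
    prior_present: float = 0.5,
) -> float:
    """Posterior weight of "present" at the root by the pruning recursion.

    ``presence`` maps genus -> True for a reported item; genera absent from
    the mapping (or mapped to False) are *missing data*, contributing partial
    likelihood 1 to both states.
    """
    if not isinstance(presence, Mapping):
        raise TypeError("presence must be a mapping genus -> bool")
    if len(presence) == 0:
        raise ValueError("empty presence map")
    tips = set(tree.tips)
    unknown = set(presence) - tips
    if unknown:
        raise KeyError(f"genera not in tree: {sorted(unknown)}")

    def partial(node) -> tuple[float, float]:
        if node.is_leaf():
            if presence.get(node.taxon.label, False):
                return (0.0, 1.0)  # (absent, present)
            return (1.0, 1.0)  # missing data
        la, lp = 1.0, 1.0
        for child in node.child_nodes():
            ca, cp = partial(child)
            same, diff = _transition(child.edge.length or 0.0, rate)
            la *= same * ca + diff * cp
            lp *= diff * ca + same * cp
        return (la, lp)

    la, lp = partial(tree.tree.seed_node)
    denom = (1.0 - prior_present) * la + prior_present * lp
    if denom == 0.0:
        return prior_present
    return prior_present * lp / denom


def felsenstein_root_weights_matrix(
    tree: Phylogeny,
    presence: pd.DataFrame,
    rate: float = 1.0,
    prior_present: float = 0.5,
) -> pd.Series:
    """Root weights for many items at once (columns of ``presence``).

    Vectorized pruning recursion: identical to
    :func:`felsenstein_root_weight` item by item, evaluated with one
    postorder sweep carrying a (2 x n_items) partial-likelihood block per
    node.  Rows of ``presence`` are genera (True = reported; False/absent =
    missing data).
    """
    items = list(presence.columns)
    m = len(items)
    if m == 0:
        return pd.Series(dtype=float)
    pres = {g: presence.loc[g].values.astype(bool) for g in presence.index}

    def block(node) -> np.ndarray:
        if node.is_leaf():
            L = np.ones((2, m))
            row = pres.get(node.taxon.label)
            if row is not None:
                L[0, row] = 0.0  # observed present: absent-state likelihood 0
            return L
        L = np.ones((2, m))
        for child in node.child_nodes():
            same, diff = _transition(child.edge.length or 0.0, rate)
            P = np.array([[same, diff], [diff, same]])
            L *= P @ block(child)
        return L

    L = block(tree.tree.seed_node)
    denom = (1.0 - prior_present) * L[0] + prior_present * L[1]
    w = np.where(denom > 0, prior_present * L[1] / np.where(denom == 0, 1, denom),
                 prior_present)
    return pd.Series(w, index=items)


def score_items(
    matrix: ReportMatrix,
    tree: Phylogeny,
    scheme: str = "correlation",
    basis: str = "reported",
    rate: float = 1.0,
) -> ItemScores:
    """Score every item of the report matrix under one weighting scheme.

    correlation: per-genus score table = basis matrix^T x correlation (each
    item gets, for every focal genus, the presence row weighted by that
    genus's correlation to the reporting genera); aggregate = column sums.
    felsenstein: one root weight per item from its presence row; the
    per-genus table repeats it on reporting genera for interface parity.
    """
    if scheme not in ("correlation", "felsenstein"):
        raise ValueError(f"unknown scheme {scheme!r}")
    B = matrix.basis(basis)  # raises on bad basis
    missing = set(matrix.genera) - set(tree.tips)
    if missing:
        raise KeyError(f"matrix genera missing from tree: {sorted(missing)}")
    if scheme == "correlation":
        corr = phylo_correlation(tree, matrix.genera)
        per_genus = pd.DataFrame(
            corr.values @ B.values.astype(float),
            index=matrix.genera,
            columns=matrix.items,
        )
        aggregate = per_genus.sum(axis=0)
    else:
        aggregate = felsenstein_root_weights_matrix(tree, B, rate=rate)
        per_genus = pd.DataFrame(
            np.tile(aggregate.values, (len(matrix.genera), 1)),
            index=matrix.genera,
            columns=matrix.items,
        )
    return ItemScores(
        per_genus=per_genus, aggregate=aggregate, scheme=scheme, basis=basis
    )
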