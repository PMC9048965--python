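"""Selecting nature-like simulations by network-topology similarity.

Every pathway-evolution outcome is reduced to 16 classical topology
descriptors per genus, concatenated in a fixed genus order (21 genera give
336 columns), deduplicated, ``log10(x+1)``-transformed and z-scaled.  A 2-D
UMAP embedding is fitted on the simulated rows; the natural naïve model is
projected repeatedly with the stochastic transform, and simulations whose
squared Mahalanobis distance to the projection cloud falls below a χ²(2)
quantile are selected as surrogates for parameter benchmarking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DESCRIPTORS",
    "network_descriptors",
    "build_feature_table",
    "embed_and_select",
]


def _largest_cc(g: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(g), key=len)
    return g.subgraph(comp)


def _safe(fn: Callable[[nx.Graph], float], default: float = 0.0):
    def wrapped(g: nx.Graph) -> float:
        try:
            v = fn(g)
        except Exception:
            return default
        if v is None or (isinstance(v, float) and not math.isfinite(v)):
            return default
        return float(v)

    return wrapped


def _degree_entropy(g: nx.Graph) -> float:
    degs = np.array([d for _, d in g.degree()], dtype=float)
    if degs.sum() == 0:
        return 0.0
    _, counts = np.unique(degs, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


# fixed, documented ordering; degenerate graphs get sentinel 0
DESCRIPTORS: list[tuple[str, Callable[[nx.Graph], float]]] = [
    ("n_nodes", _safe(nx.number_of_nodes)),
    ("n_edges", _safe(nx.number_of_edges)),
    ("density", _safe(nx.density)),
    ("mean_degree", _safe(lambda g: 2 * g.number_of_edges() / g.number_of_nodes())),
    ("degree_variance", _safe(lambda g: float(np.var([d for _, d in g.degree()])))),
    ("n_components", _safe(nx.number_connected_components)),
    ("largest_component", _safe(lambda g: len(max(nx.connected_components(g), key=len)))),
    ("diameter_lcc", _safe(lambda g: nx.diameter(_largest_cc(g)))),
    ("radius_lcc", _safe(lambda g: nx.radius(_largest_cc(g)))),
    ("mean_clustering", _safe(nx.average_clustering)),
    ("n_articulation", _safe(lambda g: len(list(nx.articulation_points(g))))),
    ("n_leaves", _safe(lambda g: sum(1 for _, d in g.degree() if d == 1))),
    ("mean_shortest_path_lcc", _safe(lambda g: nx.average_shortest_path_length(_largest_cc(g)))),
    ("assortativity", _safe(nx.degree_assortativity_coefficient)),
    ("cycle_rank", _safe(lambda g: g.number_of_edges() - g.number_of_nodes()
                         + nx.number_connected_components(g))),
    ("degree_entropy", _safe(_degree_entropy)),
]


def network_descriptors(g: nx.Graph) -> np.ndarray:
    """The 16-component topology descriptor vector of one pathway graph."""
    if g.number_of_nodes() == 0:
        return np.zeros(len(DESCRIPTORS))
    return np.array([fn(g) for _, fn in DESCRIPTORS])


def build_feature_table(
    sets: Sequence[Mapping[str, nx.Graph]],
    genera: Sequence[str],
    set_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Concatenate per-genus descriptors, dedup, log10(x+1), z-scale.

    One row per pathway set; columns are ``genus:descriptor`` in the fixed
    genus order (16 x len(genera) columns).  Zero-variance columns z-scale
    to 0.
    """
    ids = list(set_ids) if set_ids is not None else [str(i) for i in range(len(sets))]
    rows = []
    for s in sets:
        missing = set(genera) - set(s)
        if missing:
            raise KeyError(f"pathway set missing genera {sorted(missing)}")
        rows.append(np.concatenate([network_descriptors(s[g]) for g in genera]))
    cols = [f"{g}:{name}" for g in genera for name, _ in DESCRIPTORS]
    table = pd.DataFrame(rows, index=ids, columns=cols)
    table = table[~table.duplicated(keep="first")]
    table = _signed_log10(table)
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=0)
    z = (table - mean) / sd.replace(0.0, np.inf)
    z.attrs["log_mean"] = mean
    z.attrs["log_sd"] = sd
    return z


def _signed_log10(x):
    """log10(x+1) extended to the few signed descriptors (assortativity):
    sign(x) * log10(1+|x|), identical to log10(x+1) for x >= 0."""
    return np.sign(x) * np.log10(1.0 + np.abs(x))


def transform_row_like(
    table: pd.DataFrame, raw_row: np.ndarray
) -> np.ndarray:
    """Apply a fitted table's log/z transform to one raw descriptor row."""
    mean = table.attrs["log_mean"].values
    sd = table.attrs["log_sd"].values
    x = _signed_log10(np.asarray(raw_row, dtype=float))
    out = (x - mean) / np.where(sd == 0.0, np.inf, sd)
    return out


def embed_and_select(
    table: pd.DataFrame,
    natural_row: np.ndarray,
    n_projections: int = 10_000,
    chi2_quantile: float = 0.99,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    ridge: float = 1e-9,
    include_natural_in_fit: bool = True,
) -> tuple[list[str], dict]:
    """UMAP + Mahalanobis selection of nature-like simulation sets.

    Fits a 2-D UMAP on the (already transformed) surrogate rows, then
    projects ``natural_row`` (same transform, same columns)
    ``n_projections`` times with varying transform seeds.  Rows whose
    squared Mahalanobis distance to the projection cloud lies below the
    ``chi2_quantile`` quantile of χ²(df=2) are selected.  Returns (selected
    ids, diagnostics).

    The natural row takes part in the manifold fit by default: projecting a
    strictly out-of-sample row carries a placement offset unrelated to
    topology similarity, which would inflate every Mahalanobis distance.
    """
    import umap  # deferred: heavy import

    X = table.values.astype(np.float32)
    nat = np.asarray(natural_row, dtype=np.float32).reshape(1, -1)
    if nat.shape[1] != X.shape[1]:
        raise ValueError("natural row has wrong width")
    fit_X = np.vstack([X, nat]) if include_natural_in_fit else X
    nn = min(n_neighbors, max(2, fit_X.shape[0] - 1))
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=nn,
        min_dist=min_dist,
        random_state=seed,
        transform_seed=seed,
    )
    emb_all = reducer.fit_transform(fit_X)
    emb = emb_all[: X.shape[0]]
    proj = np.empty((n_projections, 2))
    for k in range(n_projections):
        reducer.transform_seed = seed + 1 + k
        proj[k] = reducer.transform(nat)[0]
    mu = proj.mean(axis=0)
    cov = np.cov(proj.T) if n_projections > 1 else np.eye(2)
    cov = np.atleast_2d(cov) + ridge * np.eye(2)
    # A projection cloud tighter than the embedding's own resolution is
    # effectively degenerate: floor the covariance at the median
    # nearest-neighbor spacing of the surrogate embedding, so the chi2 gate
    # selects sets within a few spacings of the natural location regardless
    # of the arbitrary scale of the transform jitter.
    if emb.shape[0] >= 2:
        dists = np.sqrt(
            ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
        )
        np.fill_diagonal(dists, np.inf)
        mednn = float(np.median(dists.min(axis=1)))
        if np.linalg.eigvalsh(cov).max() < mednn**2:
            cov = cov + mednn**2 * np.eye(2)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_inv = np.linalg.inv(cov + 1e-6 * np.eye(2))
    d = emb - mu
    md2 = np.einsum("ij,jk,ik->i", d, cov_inv, d)
    cut = stats.chi2.ppf(chi2_quantile, df=2)
    selected = [table.index[i] for i in np.where(md2 < cut)[0]]
    diag = {
        "embedding": emb,
        "projections": proj,
        "mahalanobis_sq": md2,
        "chi2_cut": float(cut),
    }
    return selected, diag
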