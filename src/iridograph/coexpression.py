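"""Guilt-by-association enzyme-candidate ranking.

Tissue expression profiles are log2(x+1)-transformed and z-scored per
transcript, mapped onto a 20x20 hexagonal self-organizing map in toroidal
space, and the 400 codebook vectors are cut into ten clusters with Ward's
criterion on Manhattan distances.  A hypergeometric test then asks which
clusters are enriched in bait transcripts (known early-pathway enzymes);
members of enriched clusters are the coexpression candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

__all__ = [
    "ExpressionMatrix",
    "CandidateRanking",
    "zscore_expression",
    "SelfOrganizingMap",
    "som_cluster",
    "enrich_and_rank",
]


@dataclass
class ExpressionMatrix:
    """Transcripts x tissues abundance matrix (FPKM-like, nonnegative)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 tissues")
        if self.values.isna().any().any():
            raise ValueError("missing cells are not allowed")
        if (self.values.values < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def transcripts(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CandidateRanking:
    """Cluster assignment, per-cluster enrichment, and the candidate list."""

    clusters: pd.Series  # transcript -> cluster id
    p_values: pd.Series | None = None  # cluster id -> enrichment p
    candidates: list[str] = field(default_factory=list)
    alpha: float | None = None


def zscore_expression(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, list[str]]:
    """log2(x+1) then per-transcript z-score; returns (matrix, flat rows).

    Transcripts with zero variance cannot be scaled; their rows are set to 0
    and their ids returned as flagged.
    """
    logged = np.log2(matrix.values + 1.0)
    mean = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=0)
    flat = sd[sd == 0.0].index.tolist()
    z = logged.sub(mean, axis=0).div(sd.replace(0.0, np.inf), axis=0)
    return z, flat


def _hex_positions(rows: int, cols: int) -> np.ndarray:
    """Axial coordinates of a hexagonal grid (offset rows)."""
    pos = np.zeros((rows * cols, 2))
    for r in range(rows):
        for c in range(cols):
            pos[r * cols + c] = (c + 0.5 * (r % 2), r * np.sqrt(3) / 2)
    return pos


class SelfOrganizingMap:
    """Batch self-organizing map on a hexagonal toroidal grid.

    Neighborhood is Gaussian in grid space with toroidal wrap-around; the
    radius decays linearly over the epochs.  Deterministic for a fixed seed.
    """

    def __init__(
        self,
        rows: int = 20,
        cols: int = 20,
        n_epochs: int = 20,
        seed: int = 0,
    ):
        self.rows = rows
        self.cols = cols
        self.n_epochs = n_epochs
        self.seed = seed
        self.positions = _hex_positions(rows, cols)
        self._span = (cols, rows * np.sqrt(3) / 2)
        self.codebook: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def _grid_dist2(self) -> np.ndarray:
        """Pairwise squared toroidal distances between neurons."""
        p = self.positions
        d = np.abs(p[:, None, :] - p[None, :, :])
        for k, span in enumerate(self._span):
            d[..., k] = np.minimum(d[..., k], span - d[..., k])
        return (d**2).sum(axis=-1)

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        n, dim = X.shape
        if n < self.n_neurons:
            warnings.warn(
                f"fewer observations ({n}) than neurons ({self.n_neurons})"
            )
        rng = np.random.default_rng(self.seed)
        init_idx = rng.integers(0, n, size=self.n_neurons)
        self.codebook = X[init_idx] + 1e-6 * rng.standard_normal(
            (self.n_neurons, dim)
        )
        grid_d2 = self._grid_dist2()
        r0 = max(self._span) / 2.0
        for epoch in range(self.n_epochs):
            radius = max(r0 * (1.0 - epoch / self.n_epochs), 0.5)
            bmu = self.predict(X)
            h = np.exp(-grid_d2[:, bmu] / (2.0 * radius**2))  # neurons x n
            weight_sum = h.sum(axis=1)
            num = h @ X
            nonzero = weight_sum > 1e-12
            self.codebook[nonzero] = num[nonzero] / weight_sum[nonzero, None]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Best-matching neuron index for every row of X."""
        if self.codebook is None:
            raise RuntimeError("fit first")
        d = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ self.codebook.T
            + (self.codebook**2).sum(axis=1)[None, :]
        )
        return np.argmin(d, axis=1)


def som_cluster(
    z: pd.DataFrame,
    rows: int = 20,
    cols: int = 20,
    n_clusters: int = 10,
    seed: int = 0,
    n_epochs: int = 20,
) -> CandidateRanking:
    """SOM + Ward-on-Manhattan clustering of transcripts.

    Transcripts are assigned to their best-matching neuron; the codebook
    vectors are hierarchically clustered (Ward's criterion on Manhattan
    distances) and cut into ``n_clusters``; a transcript inherits its
    neuron's cluster.
    """
    som = SelfOrganizingMap(rows=rows, cols=cols, seed=seed, n_epochs=n_epochs)
    X = z.values
    som.fit(X)
    bmu = som.predict(X)
    d = pdist(som.codebook, metric="cityblock")
    link = linkage(d, method="ward")
    neuron_cluster = fcluster(link, t=n_clusters, criterion="maxclust")
    clusters = pd.Series(neuron_cluster[bmu], index=z.index, name="cluster")
    return CandidateRanking(clusters=clusters)


def enrich_and_rank(
    ranking: CandidateRanking,
    baits: set[str],
    alpha: float = 0.05,
) -> CandidateRanking:
    """Hypergeometric bait enrichment per cluster; candidates from clusters
    with p < alpha, ranked by p."""
    clusters = ranking.clusters
    baits = set(baits)
    if not baits:
        raise ValueError("empty bait set")
    unknown = baits - set(clusters.index)
    if unknown:
        raise KeyError(f"baits not in expression matrix: {sorted(unknown)}")
    m_total = len(clusters)
    n_baits = len(baits)
    pvals = {}
    for cid, members in clusters.groupby(clusters):
        size = len(members)
        k = len(set(members.index) & baits)
        # upper tail: P[X >= k]
        pvals[cid] = float(hypergeom.sf(k - 1, m_total, n_baits, size))
    p = pd.Series(pvals).sort_values()
    enriched = p[p < alpha].index.tolist()
    candidates = [
        t
        for cid in enriched
        for t in clusters[clusters == cid].index
    ]
    return CandidateRanking(
        clusters=clusters, p_values=p, candidates=candidates, alpha=alpha
    )
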