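"""Expression-matrix preprocessing: gene filtering, feature selection,
dimensionality choice, and clustering with a Rand-index stability criterion.

The feature-selection and PC rules follow the standard droplet-workflow
conventions: dispersion-based highly-variable-gene ranking inside
equal-frequency mean-expression bins, and a "smallest number of PCs
explaining >= 25% of total variance, floor 50, cap 100" rule.  Clustering is
modularity-based community detection on a Jaccard-weighted k-nearest-neighbor
graph in PC space; the stability criterion (pairwise Rand index > 0.8 between
partitions at adjacent k) is what the module guarantees, the community
detector itself is pluggable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from anndata import AnnData
from scipy import sparse
from sklearn.metrics import rand_score
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "PCDecision",
    "filter_genes_min_cells",
    "select_highly_variable",
    "choose_pcs",
    "knn_cluster",
    "clustering_stability",
    "pairwise_rand_index",
]


@dataclass
class PCDecision:
    """The PC-count rule and its outcome.

    ``chosen_pcs`` is the smallest number of PCs explaining at least
    ``variance_target`` of total variance, floored at ``min_pcs`` and capped
    at ``max_pcs``; ``explained`` records the variance fraction of the
    chosen set.
    """

    variance_target: float = 0.25
    min_pcs: int = 50
    max_pcs: int = 100
    chosen_pcs: int | None = None
    explained: float | None = None


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


def filter_genes_min_cells(adata: AnnData, min_cells: int = 10) -> AnnData:
    """Retain genes with nonzero expression in at least ``min_cells`` cells.

    Returns a view-free copy; the number of removed genes lands in
    ``adata.uns["n_genes_removed"]``.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    x = adata.X
    if sparse.issparse(x):
        n_cells_per_gene = np.asarray((x != 0).sum(axis=0)).ravel()
    else:
        n_cells_per_gene = np.count_nonzero(np.asarray(x), axis=0)
    keep = n_cells_per_gene >= min_cells
    if not keep.any():
        raise ValueError("no genes pass the min_cells filter")
    out = adata[:, keep].copy()
    out.uns["n_genes_removed"] = int((~keep).sum())
    return out


def select_highly_variable(
    adata: AnnData, n_top: int, n_bins: int = 20
) -> list[str]:
    """Rank genes by binned, z-scored dispersion and return the top ``n_top``.

    Genes are placed into ``n_bins`` equal-frequency mean-expression bins;
    the dispersion (variance/mean) is z-scored within each bin and genes are
    ranked by the z-scored dispersion.  Ties break lexicographically on the
    gene id for determinism.  Bins whose dispersions are all equal fall back
    to the raw dispersion with a logged warning.
    """
    if n_top > adata.n_vars:
        raise ValueError("n_top exceeds the number of genes")
    x = _dense(adata.X)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)

    # equal-frequency bins on the mean, with value-based edges so that
    # genes with identical means always share a bin
    edges = np.unique(
        np.percentile(mean, np.linspace(0, 100, n_bins + 1)[1:-1])
    )
    bin_ids = np.digitize(mean, edges)

    z = np.zeros_like(dispersion)
    for b in np.unique(bin_ids):
        idx = bin_ids == b
        d = dispersion[idx]
        sd = d.std()
        if sd == 0:
            logger.warning(
                "dispersion bin %d degenerate (all-equal dispersion); "
                "falling back to raw dispersion ranking",
                b,
            )
            z[idx] = d
        else:
            z[idx] = (d - d.mean()) / sd

    gene_ids = np.asarray(adata.var_names)
    # sort by (-z, gene_id) for a deterministic ranking
    ranked = sorted(range(len(gene_ids)), key=lambda i: (-z[i], gene_ids[i]))
    return [gene_ids[i] for i in ranked[:n_top]]


def union_features(hvgs: list[str], markers: list[str], present: list[str]) -> list[str]:
    """Union of HVGs with marker genes restricted to genes present."""
    present_set = set(present)
    out = list(dict.fromkeys(list(hvgs) + [m for m in markers if m in present_set]))
    return out


def choose_pcs(
    adata: AnnData, decision: PCDecision | None = None
) -> tuple[np.ndarray, PCDecision]:
    """PCA on per-gene-centered values with the min-50/25%-target/100-cap rule.

    Returns (cell x chosen_pcs score matrix, completed PCDecision).  When the
    matrix has fewer than ``min_pcs`` possible components the count is capped
    at ``min(n_cells - 1, n_genes)`` with a warning.
    """
    decision = decision or PCDecision()
    x = _dense(adata.X).astype(float)
    x = x - x.mean(axis=0)
    n_cells, n_genes = x.shape
    max_rank = min(n_cells - 1, n_genes)
    if max_rank < 1:
        raise ValueError("need at least 2 cells and 1 gene for PCA")

    # full SVD of the centered matrix; eigenvalues of the covariance
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ev = (s**2) / (n_cells - 1)
    total_var = x.var(axis=0, ddof=1).sum()
    cum = np.cumsum(ev) / total_var

    n_target = int(np.searchsorted(cum, decision.variance_target) + 1)
    chosen = max(decision.min_pcs, n_target)
    chosen = min(chosen, decision.max_pcs)
    if chosen > max_rank:
        warnings.warn(
            f"requested {chosen} PCs but rank allows only {max_rank}; capping",
            stacklevel=2,
        )
        chosen = max_rank

    decision.chosen_pcs = chosen
    decision.explained = float(cum[chosen - 1])
    scores = u[:, :chosen] * s[:chosen]
    return scores, decision


def _jaccard_knn_graph(pc_scores: np.ndarray, k: int):
    """Jaccard-weighted k-NN graph (igraph) in Euclidean PC space."""
    import igraph as ig

    n = pc_scores.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(pc_scores)
    _, idx = nn.kneighbors(pc_scores)
    neighbor_sets = [set(row[1:]) for row in idx]  # drop self

    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in neighbor_sets[i]:
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neighbor_sets[a] & neighbor_sets[b])
            union = len(neighbor_sets[a] | neighbor_sets[b])
            w = inter / union if union else 0.0
            if w > 0:
                edges.append((a, b))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def knn_cluster(pc_scores: np.ndarray, k: int = 20, seed: int = 0) -> np.ndarray:
    """Leiden modularity communities on a Jaccard-weighted k-NN graph.

    Deterministic given ``seed``; returns integer labels per cell.
    """
    import leidenalg

    if k <= 0:
        raise ValueError("k must be positive")
    pc_scores = np.asarray(pc_scores)
    if k >= pc_scores.shape[0]:
        raise ValueError("k must be smaller than the number of cells")
    g = _jaccard_knn_graph(pc_scores, k)
    part = leidenalg.find_partition(
        g,
        leidenalg.ModularityVertexPartition,
        weights="weight",
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)


def pairwise_rand_index(a, b) -> float:
    """Plain (unadjusted) Rand index between two partitions."""
    return float(rand_score(a, b))


def clustering_stability(
    partitions: dict[int, np.ndarray], threshold: float = 0.8
) -> tuple[int | None, np.ndarray, list[int]]:
    """Select the smallest k stable against the next larger k values.

    ``partitions`` maps the k-NN parameter to a partition of the same cells.
    Returns (selected k or None, full pairwise Rand matrix in ascending-k
    order, the sorted k values).  A k is stable when its Rand indices against
    the next two larger k values (or all remaining, if fewer) exceed
    ``threshold``.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    ks = sorted(partitions)
    m = len(ks)
    rand = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            rand[i, j] = rand[j, i] = pairwise_rand_index(
                partitions[ks[i]], partitions[ks[j]]
            )
    selected = None
    for i, k in enumerate(ks[:-1]):
        upper = rand[i, i + 1 : min(i + 3, m)]
        if np.all(upper > threshold):
            selected = k
            break
    return selected, rand, ks
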