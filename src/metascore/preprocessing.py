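"""QC, normalization, HVG selection, embedding, clustering and
malignant-cell isolation.

The chain is order-fixed: QC (cells, then genes) -> per-cell
normalization + log1p -> binned-dispersion HVG selection -> PCA ->
kNN graph -> Louvain. Every step is deterministic given its seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig
from .errors import ConfigError, DataError, EmptyDataError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """PCA scores (cells x n_pcs) with explained-variance fractions."""

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # n_pcs x n_genes loadings

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio)
        if np.any(np.diff(evr) > 1e-12) or np.any(evr < -1e-12) or np.any(evr > 1 + 1e-12):
            raise DataError("explained-variance fractions must be non-increasing in [0, 1]")


def qc_metrics(m: ExpressionMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell detected genes, total counts and mitochondrial fraction."""
    total = m.X.sum(axis=1)
    detected = (m.X > 0).sum(axis=1)
    mito = np.array([g.startswith(mito_prefix) for g in m.gene_ids])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, m.X[:, mito].sum(axis=1) / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "n_genes_detected": detected.astype(int),
            "total_counts": total,
            "mito_frac": mito_frac,
        }
    )


def qc_filter(m: ExpressionMatrix, cfg: PipelineConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove low-quality cells, then rarely detected genes.

    Cells with fewer detected genes than ``min_genes_per_cell`` or a
    mitochondrial fraction above ``max_mito_frac`` are dropped first;
    genes detected in fewer than ``min_cells_per_gene`` of the surviving
    cells are dropped second.
    """
    if m.layer != "counts":
        raise DataError("qc_filter expects the counts layer")
    qc = qc_metrics(m, cfg.mito_prefix)
    keep_cells = (
        (qc["n_genes_detected"].to_numpy() >= cfg.min_genes_per_cell)
        & (qc["mito_frac"].to_numpy() <= cfg.max_mito_frac)
    )
    qc["pass_qc"] = keep_cells
    if not keep_cells.any():
        raise EmptyDataError("QC removed every cell")
    filtered = m.subset_cells(keep_cells)
    detected_in = (filtered.X > 0).sum(axis=0)
    keep_genes = detected_in >= cfg.min_cells_per_gene
    if not keep_genes.any():
        raise EmptyDataError("QC removed every gene")
    filtered = filtered.subset_genes(keep_genes)
    logger.info(
        "QC kept %d/%d cells and %d/%d genes",
        filtered.n_cells, m.n_cells, filtered.n_genes, m.n_genes,
    )
    return filtered, qc


def normalize_log1p(m: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then ln(1 + x)."""
    if m.layer != "counts":
        raise DataError("normalize_log1p expects the counts layer")
    totals = m.X.sum(axis=1)
    if (totals <= 0).any():
        raise DataError("normalize_log1p reached a zero-total cell; run QC first")
    scaled = m.X * (target_sum / totals)[:, None]
    out = ExpressionMatrix.__new__(ExpressionMatrix)
    out.X = np.log1p(scaled)
    out.cell_ids = list(m.cell_ids)
    out.gene_ids = list(m.gene_ids)
    out.layer = "lognorm"
    return out


def select_hvg(m: ExpressionMatrix, n_hvg: int, n_mean_bins: int = 20) -> np.ndarray:
    """Top ``n_hvg`` genes by within-mean-bin z-scored dispersion.

    Dispersion is variance/mean of the log-normalized values. Genes are
    cut into ``n_mean_bins`` equal-count bins of mean expression and the
    dispersion is z-scored inside each bin; ties in the final ranking
    break by gene index.
    """
    if m.layer != "lognorm":
        raise DataError("select_hvg expects the lognorm layer")
    n_genes = m.n_genes
    if n_hvg > n_genes:
        raise ConfigError(f"n_hvg={n_hvg} exceeds the {n_genes} available genes")
    mean = m.X.mean(axis=0)
    var = m.X.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    # tied means share a rank (and hence a bin)
    ranks = scipy.stats.rankdata(mean, method="average") - 1.0
    n_bins_eff = min(n_mean_bins, n_genes)
    bins = np.minimum((ranks * n_bins_eff / n_genes).astype(np.int64), n_bins_eff - 1)
    z = np.zeros(n_genes)
    for b in np.unique(bins):
        in_bin = bins == b
        mu, sd = disp[in_bin].mean(), disp[in_bin].std()
        if sd > 0:
            z[in_bin] = (disp[in_bin] - mu) / sd
    # stable sort on -z keeps gene-index order among ties
    top = np.argsort(-z, kind="stable")[:n_hvg]
    return np.sort(top)


def pca_embed(m: ExpressionMatrix | np.ndarray, n_pcs: int) -> Embedding:
    """PCA of the gene-centered matrix via SVD.

    Scores are left singular vectors scaled by singular values. Each
    component's sign is fixed so its largest-magnitude loading is
    positive. Requests beyond the matrix rank are truncated with a
    warning.
    """
    x = m.X if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=np.float64)
    n_cells, n_genes = x.shape
    if n_pcs > min(n_cells - 1, n_genes):
        raise ConfigError(
            f"n_pcs={n_pcs} exceeds min(cells-1, genes) = {min(n_cells - 1, n_genes)}"
        )
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = float((s ** 2).sum())
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise DataError("matrix is constant; no principal direction")
    k = min(n_pcs, rank)
    if k < n_pcs:
        warnings.warn(f"requested {n_pcs} PCs but rank is {rank}; truncating")
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    return Embedding(
        scores=u * s,
        explained_variance_ratio=(s ** 2) / total_var,
        components=vt,
    )


def knn_graph(embedding: Embedding | np.ndarray, k: int) -> nx.Graph:
    """Undirected kNN graph (Euclidean, union-symmetrized, weight 1)."""
    pts = embedding.scores if isinstance(embedding, Embedding) else np.asarray(embedding)
    n = pts.shape[0]
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto", metric="euclidean")
    nn.fit(pts)
    _, idx = nn.kneighbors(pts)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        for j in neigh:
            g.add_edge(i, int(j), weight=1.0)
    return g


def louvain_cluster(g: nx.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Louvain modularity clustering; ids relabeled by decreasing size.

    Ties in community size break by the smallest contained node id.
    """
    if g.number_of_nodes() == 0:
        raise EmptyDataError("cannot cluster an empty graph")
    comms = nx.community.louvain_communities(g, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(g.number_of_nodes(), dtype=np.int64)
    nodes = sorted(g.nodes())
    node_pos = {v: i for i, v in enumerate(nodes)}
    for cid, comm in enumerate(comms):
        for v in comm:
            labels[node_pos[v]] = cid
    return labels


def flag_malignant(
    cluster_ids: np.ndarray,
    malignant_score: np.ndarray | None = None,
    user_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell malignant flags.

    User-supplied labels pass through unchanged. Otherwise a cluster is
    flagged malignant when its mean malignant-signature score strictly
    exceeds the median of the per-cluster means.
    """
    cluster_ids = np.asarray(cluster_ids)
    if user_labels is not None:
        labels = np.asarray(user_labels, dtype=bool)
        if labels.shape != cluster_ids.shape:
            raise DataError("user malignant labels do not match the cell count")
        return labels
    if malignant_score is None:
        raise ConfigError("need either user labels or a malignant signature score")
    score = np.asarray(malignant_score, dtype=np.float64)
    if score.shape != cluster_ids.shape:
        raise DataError("malignant score does not match the cell count")
    cluster_means = pd.Series(score).groupby(pd.Series(cluster_ids)).mean()
    median = float(cluster_means.median())
    flagged_clusters = set(cluster_means.index[cluster_means > median])
    return np.array([c in flagged_clusters for c in cluster_ids])
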