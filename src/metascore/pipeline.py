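"""End-to-end scoring pipeline: preprocessing, malignant isolation,
signature scoring, initiation features/score, and downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ConfigError, EmptyDataError
from .initiation import IntegrationModel, compute_initiation
from .io import ExpressionMatrix, GeneSetCollection
from .preprocessing import (
    flag_malignant,
    knn_graph,
    louvain_cluster,
    normalize_log1p,
    pca_embed,
    qc_filter,
    select_hvg,
)
from .scoring import score_gene_set, score_signatures
from .stats import ora_enrichment, rank_sum_de

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    per_cell: pd.DataFrame
    cluster_table: pd.DataFrame
    de_table: pd.DataFrame
    ora_table: pd.DataFrame
    qc_table: pd.DataFrame
    model: IntegrationModel
    threshold: float
    summary: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "per_cell": self.per_cell,
            "per_cluster": self.cluster_table,
            "de": self.de_table,
            "ora": self.ora_table,
            "qc": self.qc_table,
        }


def _cluster_cells(m: ExpressionMatrix, cfg: PipelineConfig) -> np.ndarray:
    """HVG -> PCA -> kNN -> Louvain on a log-normalized matrix."""
    n_hvg = min(cfg.n_hvg, m.n_genes)
    hvg = select_hvg(m, n_hvg)
    n_pcs = min(cfg.n_pcs, m.n_cells - 1, n_hvg)
    emb = pca_embed(m.subset_genes(hvg), n_pcs)
    k = min(cfg.knn_k, m.n_cells - 1)
    graph = knn_graph(emb, k)
    return louvain_cluster(graph, cfg.louvain_resolution, cfg.cluster_seed)


def run_pipeline(
    counts: ExpressionMatrix,
    signatures: GeneSetCollection,
    cfg: PipelineConfig,
    malignant_labels: pd.Series | None = None,
    extra_features: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full analysis on a raw counts matrix.

    ``malignant_labels`` (boolean, indexed by cell id) override
    marker-based malignant calling; otherwise the signature collection
    must contain a ``malignant`` set. ``extra_features`` are optional
    per-cell [0, 1] covariates appended to the PCA feature matrix.
    """
    signatures.validate_required()
    filtered, qc_table = qc_filter(counts, cfg)
    lognorm = normalize_log1p(filtered, cfg.target_sum)

    # global clustering over all retained cells, for malignant calling
    global_clusters = _cluster_cells(lognorm, cfg)

    if malignant_labels is not None:
        labels = malignant_labels.reindex(lognorm.cell_ids)
        if labels.isna().any():
            raise ConfigError("malignant labels missing for some retained cells")
        flags = flag_malignant(global_clusters, user_labels=labels.to_numpy(dtype=bool))
    else:
        if "malignant" not in signatures:
            raise ConfigError(
                "no malignant labels given and the signature collection has "
                "no 'malignant' set"
            )
        mal_score = score_gene_set(
            lognorm, signatures["malignant"], cfg.n_bins, cfg.ctrl_size, cfg.score_seed
        )
        flags = flag_malignant(global_clusters, malignant_score=mal_score)
    if not flags.any():
        raise EmptyDataError("no cell was called malignant")

    malignant = lognorm.subset_cells(flags)
    # re-cluster the malignant subpopulation for state mapping
    mal_clusters = _cluster_cells(malignant, cfg)

    raw_scores = score_signatures(malignant, signatures, cfg)
    per_cell, model, cluster_table, threshold = compute_initiation(
        raw_scores, mal_clusters, cfg, extra_features=extra_features
    )

    de_table = rank_sum_de(malignant, per_cell["high_init_flag"].to_numpy())
    sig_up = de_table.loc[
        (de_table["q_value"] < cfg.alpha) & (de_table["log2fc"] > 0), "gene"
    ].tolist()
    ora_table = ora_enrichment(sig_up, signatures, list(malignant.gene_ids))

    per_cell = per_cell.reset_index()
    lead = [
        "cell_id", "E", "M", "D", "S", "G", "O",
        "E_hat", "M_hat", "H", "S_hat", "D_hat", "G_hat", "O_hat",
        "R", "R_hat", "initiation_score", "hybrid_flag", "high_init_flag", "cluster",
    ]
    rest = [c for c in per_cell.columns if c not in lead]
    per_cell = per_cell[[c for c in lead if c in per_cell.columns] + rest]
    summary = {
        "n_cells_input": counts.n_cells,
        "n_cells_retained": lognorm.n_cells,
        "n_malignant": int(flags.sum()),
        "n_high_initiation": int(per_cell["high_init_flag"].sum()),
        "initiation_threshold": float(threshold),
        "mean_initiation_score": float(per_cell["initiation_score"].mean()),
        "min_initiation_score": float(per_cell["initiation_score"].min()),
        "max_initiation_score": float(per_cell["initiation_score"].max()),
        "top_cluster": int(cluster_table.iloc[0]["cluster"]),
        "top_cluster_mean": float(cluster_table.iloc[0]["mean_score"]),
        "integration_weights": {
            name: float(w) for name, w in zip(model.feature_names, model.weights)
        },
        "n_significant_up": len(sig_up),
    }
    return PipelineResult(
        per_cell=per_cell,
        cluster_table=cluster_table,
        de_table=de_table,
        ora_table=ora_table,
        qc_table=qc_table,
        model=model,
        threshold=float(threshold),
        summary=summary,
    )
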