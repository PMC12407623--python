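"""Composite initiation features and the PC1-weighted Molecular
Initiation Score.

Feature construction: normalized epithelial/mesenchymal scores give the
hybrid-EMT score H = min(E_hat, M_hat); normalized glycolysis/OXPHOS
scores give the metabolic-reprogramming ratio R = (G_hat + eps) /
(O_hat + eps). The normalized features (D_hat, H, S_hat, R_hat, plus any
user-supplied extras) are integrated with convex weights derived from
the first principal component, so the score stays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_FEATURE_ORDER, PipelineConfig
from .errors import ConfigError, DataError, EmptyDataError
from .scoring import minmax_normalize


def hybrid_emt(e_hat: np.ndarray, m_hat: np.ndarray) -> np.ndarray:
    """Elementwise minimum of the normalized epithelial and mesenchymal
    scores: high only when both programs are co-expressed."""
    e_hat = np.asarray(e_hat, dtype=np.float64)
    m_hat = np.asarray(m_hat, dtype=np.float64)
    if e_hat.shape != m_hat.shape:
        raise DataError("epithelial and mesenchymal score vectors differ in length")
    return np.minimum(e_hat, m_hat)


def classify_top_quantile(x: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    """Flag the cells at or above the q-th quantile of ``x``.

    The threshold t is the linearly interpolated order statistic at
    index h = q * (n - 1) (numpy's default quantile convention); flags
    are ``x >= t``, so ties at the threshold are included.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise EmptyDataError("cannot classify an empty vector")
    if not 0.0 < q < 1.0:
        raise ConfigError(f"quantile must lie in (0, 1), got {q}")
    t = float(np.quantile(x, q, method="linear"))
    return x >= t, t


def metabolic_ratio(g_hat: np.ndarray, o_hat: np.ndarray, epsilon: float) -> np.ndarray:
    """Glycolysis-to-OXPHOS ratio (G_hat + eps) / (O_hat + eps) on
    normalized scores; the pseudocount keeps the ratio defined at 0."""
    if epsilon <= 0:
        raise ConfigError(f"epsilon must be positive, got {epsilon}")
    g_hat = np.asarray(g_hat, dtype=np.float64)
    o_hat = np.asarray(o_hat, dtype=np.float64)
    if g_hat.shape != o_hat.shape:
        raise DataError("glycolysis and OXPHOS score vectors differ in length")
    return (g_hat + epsilon) / (o_hat + epsilon)


@dataclass
class IntegrationModel:
    """PC1-derived convex feature weights."""

    feature_names: tuple[str, ...]
    loadings: np.ndarray
    weights: np.ndarray
    sign_flipped: bool

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise DataError("weights must be non-negative and sum to 1")


def fit_integration(
    features: pd.DataFrame, anchor: str | None = None
) -> IntegrationModel:
    """PC1 loadings of the centered feature matrix, turned into convex
    weights w = |loading| / sum|loading|.

    The global sign is flipped if needed so the loading on ``anchor``
    (first column by default) is non-negative; the flip is recorded.
    """
    if features.shape[1] < 2:
        raise ConfigError("need at least two features to fit integration weights")
    if features.shape[0] < 3:
        raise ConfigError("need at least three cells to fit integration weights")
    x = features.to_numpy(dtype=np.float64)
    centered = x - x.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-300):
        raise DataError("all features are constant; no principal direction")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[0].copy()
    anchor = anchor if anchor is not None else features.columns[0]
    try:
        ai = list(features.columns).index(anchor)
    except ValueError as exc:
        raise ConfigError(f"anchor feature {anchor!r} not in feature matrix") from exc
    flipped = loadings[ai] < 0
    if flipped:
        loadings = -loadings
    weights = np.abs(loadings) / np.abs(loadings).sum()
    return IntegrationModel(
        feature_names=tuple(features.columns),
        loadings=loadings,
        weights=weights,
        sign_flipped=bool(flipped),
    )


def initiation_score(features: pd.DataFrame, model: IntegrationModel) -> np.ndarray:
    """Convex combination I = F . w of the [0, 1] features."""
    if tuple(features.columns) != model.feature_names:
        raise ConfigError(
            f"feature order {tuple(features.columns)} does not match the "
            f"fitted model {model.feature_names}"
        )
    return features.to_numpy(dtype=np.float64) @ model.weights


def aggregate_by_cluster(scores: np.ndarray, cluster_ids: np.ndarray) -> pd.DataFrame:
    """Per-cluster mean score, ranked descending (ties by cluster id)."""
    scores = np.asarray(scores, dtype=np.float64)
    cluster_ids = np.asarray(cluster_ids)
    if scores.shape != cluster_ids.shape:
        raise DataError("score and cluster-id vectors differ in length")
    df = pd.DataFrame({"cluster": cluster_ids, "score": scores})
    agg = (
        df.groupby("cluster")["score"]
        .agg(n_cells="size", mean_score="mean")
        .reset_index()
    )
    agg = agg.sort_values(
        ["mean_score", "cluster"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    agg["rank"] = np.arange(1, len(agg) + 1)
    agg["n_cells"] = agg["n_cells"].astype(int)
    return agg


def compute_initiation(
    raw_scores: pd.DataFrame,
    cluster_ids: np.ndarray,
    cfg: PipelineConfig,
    extra_features: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, IntegrationModel, pd.DataFrame, float]:
    """Full feature construction + integration over malignant cells.

    ``raw_scores`` holds columns E, M, D, S, G, O (one row per malignant
    cell). Returns the per-cell table, the fitted model, the per-cluster
    aggregate and the realized high-initiation threshold.
    """
    per_cell = raw_scores.copy()
    for col in ("E", "M", "D", "S", "G", "O"):
        if col not in per_cell.columns:
            raise DataError(f"raw score column {col!r} missing")
        per_cell[f"{col}_hat"] = minmax_normalize(per_cell[col].to_numpy())
    per_cell["H"] = hybrid_emt(per_cell["E_hat"].to_numpy(), per_cell["M_hat"].to_numpy())
    hybrid_flag, _ = classify_top_quantile(per_cell["H"].to_numpy(), cfg.q_hybrid)
    per_cell["hybrid_flag"] = hybrid_flag
    per_cell["R"] = metabolic_ratio(
        per_cell["G_hat"].to_numpy(), per_cell["O_hat"].to_numpy(), cfg.epsilon
    )
    per_cell["R_hat"] = minmax_normalize(per_cell["R"].to_numpy())

    feature_cols = list(DEFAULT_FEATURE_ORDER)
    features = per_cell[feature_cols]
    if extra_features is not None:
        extra = extra_features.reindex(per_cell.index)
        if extra.isna().any().any():
            raise DataError("extra features missing for some malignant cells")
        for c in extra.columns:
            vals = extra[c].to_numpy(dtype=np.float64)
            if vals.min() < 0 or vals.max() > 1:
                raise DataError(f"extra feature {c!r} must be normalized to [0, 1]")
        features = pd.concat([features, extra], axis=1)
    model = fit_integration(features, anchor="D_hat")
    per_cell["initiation_score"] = initiation_score(features, model)
    high_flag, threshold = classify_top_quantile(
        per_cell["initiation_score"].to_numpy(), cfg.q_init
    )
    per_cell["high_init_flag"] = high_flag
    per_cell["cluster"] = np.asarray(cluster_ids)
    cluster_table = aggregate_by_cluster(
        per_cell["initiation_score"].to_numpy(), per_cell["cluster"].to_numpy()
    )
    return per_cell, model, cluster_table, threshold
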