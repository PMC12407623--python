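"""Run configuration for the scoring pipeline.

All thresholds and seeds that influence any numeric output live here, so
that a run is fully determined by (input files, PipelineConfig).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Parameters of the scoring pipeline.

    Attributes
    ----------
    min_genes_per_cell, min_cells_per_gene, max_mito_frac
        QC thresholds; cells are filtered before genes.
    mito_prefix
        Gene-id prefix identifying mitochondrial genes.
    target_sum
        Per-cell total after count normalization, before log1p.
    n_hvg
        Number of highly variable genes kept for embedding.
    n_pcs, knn_k, louvain_resolution, cluster_seed
        Embedding/clustering parameters.
    n_bins, ctrl_size, score_seed
        Signature-scoring control-matching parameters.
    epsilon
        Pseudocount of the glycolysis/OXPHOS ratio.
    q_hybrid, q_init
        Upper-quantile cutoffs for the hybrid-EMT flag (top 20% by
        default) and the high-initiation flag (top 25% by default).
    alpha
        BH false-discovery-rate level for "significant" genes/sets.
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_frac: float = 0.2
    mito_prefix: str = "MT-"
    target_sum: float = 1e4
    n_hvg: int = 2000
    n_pcs: int = 50
    knn_k: int = 15
    louvain_resolution: float = 1.0
    cluster_seed: int = 0
    n_bins: int = 25
    ctrl_size: int = 50
    score_seed: int = 0
    epsilon: float = 0.01
    q_hybrid: float = 0.80
    q_init: float = 0.75
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("q_hybrid", "q_init"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {q}")
        if self.epsilon <= 0:
            raise ConfigError(f"epsilon must be positive, got {self.epsilon}")
        for name in ("min_cells_per_gene", "n_hvg", "n_pcs", "knn_k",
                     "n_bins", "ctrl_size"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if not (isinstance(self.min_genes_per_cell, int)
                and self.min_genes_per_cell >= 0):
            raise ConfigError("min_genes_per_cell must be a non-negative integer")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ConfigError("max_mito_frac must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded in run reports."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# default order of the normalized features entering PC1 integration
DEFAULT_FEATURE_ORDER: tuple[str, ...] = ("D_hat", "H", "S_hat", "R_hat")

REQUIRED_SET_NAMES: tuple[str, ...] = (
    "epithelial", "mesenchymal", "emt_drivers", "stemness", "glycolysis", "oxphos",
)
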