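"""Per-cell gene-signature scoring with expression-matched controls.

score = mean expression over signature genes minus mean expression over
a pooled control set drawn from the same mean-expression bins as the
signature genes. The exact randomness contract is documented on
:func:`score_gene_set` so independent implementations can reproduce it
bit for bit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import ConfigError, DataError, EmptyDataError
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


def expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bins of genes by mean expression.

    Genes are ranked by mean (stable sort, ties keep gene-index order)
    and gene at rank r goes to bin floor(r * n_bins / n_genes).
    """
    n_genes = mean_expr.shape[0]
    order = np.argsort(mean_expr, kind="stable")
    ranks = np.empty(n_genes, dtype=np.int64)
    ranks[order] = np.arange(n_genes)
    return (ranks * n_bins) // n_genes


def score_gene_set(
    m: ExpressionMatrix,
    signature: list[str],
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Signature score per cell against expression-matched controls.

    Randomness contract (part of the public interface, relied on by the
    test oracles): a single ``numpy.random.default_rng(seed)`` stream;
    signature genes are visited in ascending gene-index order; for each,
    ``rng.choice(pool, size, replace=False, shuffle=False)`` draws from
    its eligible pool sorted ascending by gene index. A pool holding
    fewer than ``ctrl_size`` non-signature genes is merged with
    neighboring bins (one step outward on both sides at a time) before
    drawing; if the pool is still smaller than ``ctrl_size`` after all
    bins are merged, the whole pool is used. Per-gene draws are pooled
    into one deduplicated control set.
    """
    if n_bins < 1 or ctrl_size < 1:
        raise ConfigError("n_bins and ctrl_size must be >= 1")
    if m.layer != "lognorm":
        raise DataError("score_gene_set expects the lognorm layer")
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    sig_idx = sorted(gene_index[g] for g in signature if g in gene_index)
    n_missing = len(signature) - len(sig_idx)
    if n_missing:
        logger.warning("%d signature genes absent from the matrix were dropped", n_missing)
    if not sig_idx:
        raise DataError("no signature gene is present in the matrix")
    n_genes = m.n_genes
    mean_expr = m.X.mean(axis=0)
    bins = expression_bins(mean_expr, n_bins)
    sig_set = set(sig_idx)
    eligible_by_bin = {
        b: np.array(
            [i for i in np.flatnonzero(bins == b) if i not in sig_set], dtype=np.int64
        )
        for b in range(n_bins)
    }

    rng = np.random.default_rng(seed)
    control: set[int] = set()
    for gi in sig_idx:
        b = int(bins[gi])
        width = 0
        pool = eligible_by_bin[b]
        while pool.size < ctrl_size and width < n_bins:
            width += 1
            lo, hi = max(0, b - width), min(n_bins - 1, b + width)
            pool = np.sort(
                np.concatenate([eligible_by_bin[bb] for bb in range(lo, hi + 1)])
            )
        if pool.size == 0:
            raise DataError(
                f"no eligible control genes for signature gene {m.gene_ids[gi]!r}"
            )
        take = min(ctrl_size, pool.size)
        chosen = rng.choice(pool, size=take, replace=False, shuffle=False)
        control.update(int(c) for c in chosen)

    ctrl_idx = np.array(sorted(control), dtype=np.int64)
    return m.X[:, sig_idx].mean(axis=1) - m.X[:, ctrl_idx].mean(axis=1)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); a constant vector maps to all zeros."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise EmptyDataError("cannot normalize an empty vector")
    if not np.isfinite(x).all():
        raise DataError("minmax_normalize requires finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


#: canonical single-letter keys of the six curated programs
SIGNATURE_KEYS = {
    "E": "epithelial",
    "M": "mesenchymal",
    "D": "emt_drivers",
    "S": "stemness",
    "G": "glycolysis",
    "O": "oxphos",
}


def score_signatures(
    m: ExpressionMatrix,
    collection: GeneSetCollection,
    cfg: PipelineConfig,
    extra_sets: list[str] | None = None,
) -> pd.DataFrame:
    """Raw per-cell scores for the six curated programs (columns E, M,
    D, S, G, O) plus any ``extra_sets`` scored under their own names."""
    collection.validate_required()
    out = {}
    for key, set_name in SIGNATURE_KEYS.items():
        out[key] = score_gene_set(
            m, collection[set_name], cfg.n_bins, cfg.ctrl_size, cfg.score_seed
        )
    for name in extra_sets or []:
        out[name] = score_gene_set(
            m, collection[name], cfg.n_bins, cfg.ctrl_size, cfg.score_seed
        )
    return pd.DataFrame(out, index=pd.Index(m.cell_ids, name="cell_id"))
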