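"""Readers/writers for the formats the pipeline touches.

Counts come in as a Matrix Market triplet directory (gene-major, as
emitted by common droplet pipelines) or as a dense CSV for toy data.
Gene sets use the tab-separated GMT convention. All result tables go out
as TSV plus a JSON run report that pins the configuration hash.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .config import REQUIRED_SET_NAMES, PipelineConfig
from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger(__name__)

LAYERS = ("counts", "lognorm")


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression matrix with a layer tag.

    ``layer == "counts"`` requires integer-valued non-negative entries;
    ``layer == "lognorm"`` holds log1p-normalized values. Entries must be
    finite in either layer.
    """

    X: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if self.layer not in LAYERS:
            raise ConfigError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.X.ndim != 2:
            raise FormatError("expression matrix must be two-dimensional")
        if self.X.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.gene_ids)} gene ids"
            )
        if not np.isfinite(self.X).all():
            raise DataError("expression matrix contains NaN or Inf")
        if self.layer == "counts":
            if (self.X < 0).any():
                raise DataError("counts layer contains negative entries")
            if not np.array_equal(self.X, np.round(self.X)):
                raise DataError("counts layer contains non-integer entries")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionMatrix(
            self.X[idx], [self.cell_ids[i] for i in idx], list(self.gene_ids), self.layer
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionMatrix(
            self.X[:, idx], list(self.cell_ids), [self.gene_ids[i] for i in idx], self.layer
        )


@dataclass
class GeneSetCollection:
    """Named, ordered gene lists (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                raise FormatError(f"gene set {name!r} contains duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def validate_required(self, required: tuple[str, ...] = REQUIRED_SET_NAMES) -> None:
        missing = [n for n in required if n not in self.sets or not self.sets[n]]
        if missing:
            raise ConfigError(f"missing or empty required gene sets: {missing}")


def read_counts(path: str | Path) -> ExpressionMatrix:
    """Read a counts matrix from an MTX triplet directory or a dense CSV.

    Matrix Market input is gene-major (genes x cells) and is transposed
    to cells x genes; a dense CSV has gene ids in the header row and cell
    ids in the first column.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_dir(path)
    if path.suffix.lower() == ".csv":
        return _read_dense_csv(path)
    raise FormatError(f"cannot read counts from {path}: expected a directory "
                      "with matrix.mtx/barcodes.tsv/features.tsv or a .csv file")


def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FormatError(f"{path} does not contain matrix.mtx")
    barcodes_f = path / "barcodes.tsv"
    features_f = path / "features.tsv"
    for f in (barcodes_f, features_f):
        if not f.exists():
            raise FormatError(f"{path} does not contain {f.name}")
    m = scipy.io.mmread(str(mtx))
    if scipy.sparse.issparse(m):
        m = m.toarray()
    m = np.asarray(m)
    barcodes = [ln.split("\t")[0] for ln in barcodes_f.read_text().splitlines() if ln]
    features = [ln.split("\t")[0] for ln in features_f.read_text().splitlines() if ln]
    n_genes, n_cells = m.shape
    if n_cells != len(barcodes):
        raise FormatError(
            f"matrix declares {n_cells} cells but barcodes.tsv lists {len(barcodes)}"
        )
    if n_genes != len(features):
        raise FormatError(
            f"matrix declares {n_genes} genes but features.tsv lists {len(features)}"
        )
    return ExpressionMatrix(m.T, barcodes, features, layer="counts")


def _read_dense_csv(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    x = df.to_numpy(dtype=np.float64)
    if not np.isfinite(x).all():
        raise DataError(f"{path} contains missing or non-finite entries")
    return ExpressionMatrix(x, [str(c) for c in df.index],
                            [str(g) for g in df.columns], layer="counts")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are dropped (first occurrence kept)
    with a warning. Required-set validation is a separate, later step.
    """
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: GMT line needs name and description")
        name, genes = parts[0], [g for g in parts[2:] if g]
        seen: dict[str, None] = {}
        for g in genes:
            if g in seen:
                warnings.warn(f"duplicate gene {g!r} in set {name!r} dropped")
            else:
                seen[g] = None
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = list(seen)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "metascore") -> None:
    lines = [
        "\t".join([name, description, *genes])
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_matrix_market(m: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write a counts matrix as matrix.mtx + barcodes.tsv + features.tsv
    (gene-major orientation, integer field)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = scipy.sparse.csr_matrix(m.X.T.astype(np.int64))
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp, field="integer")
    (out / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
    (out / "features.tsv").write_text("\n".join(m.gene_ids) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: PipelineConfig, extra_report: dict | None = None) -> dict:
    """Write every result table as TSV plus ``report.json``.

    The report records the config, its hash and any caller-supplied
    provenance so a run can be reproduced exactly.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    for name, df in tables.items():
        write_table(df, out / f"{name}.tsv")
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "tables": sorted(tables),
    }
    if extra_report:
        report.update(extra_report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
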