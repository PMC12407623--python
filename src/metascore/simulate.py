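"""Seeded synthetic snRNA-seq generator with planted ground truth.

A deliberately simple but faithful generative model: per-gene baseline
rates, multiplicative (log-additive) program activation in carrier
cells, softmax-normalized expected expression scaled by log-normal
library sizes, and negative-binomial (gamma-Poisson) counts. Seven
programs are planted: the six curated scoring programs plus a
"malignant" marker program used for marker-based malignant-cell
calling; hybrid cells carry both EMT programs at half effect.

The "aggressive" ground-truth flag (hybrid AND stem-like AND
glycolytic) is a harness convention for parameter-recovery tests, not a
biological claim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .errors import ConfigError, DataError
from .io import ExpressionMatrix, GeneSetCollection, write_gmt, write_matrix_market

PROGRAM_NAMES = (
    "epithelial", "mesenchymal", "emt_drivers", "stemness",
    "glycolysis", "oxphos", "malignant",
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Fractions of hybrid, mesenchymal, stem-like and glycolytic cells are
    taken over malignant cells; the remaining malignant cells are
    epithelial / non-stem / oxidative. ``effect_size`` is the natural-log
    fold activation of a program's genes in carrier cells. ``dispersion``
    is the NB inverse-dispersion (variance = mu + mu^2 / dispersion).
    """

    n_cells: int = 2000
    n_genes: int = 2000
    frac_malignant: float = 0.5
    frac_hybrid: float = 0.20
    frac_mesenchymal: float = 0.25
    frac_stem: float = 0.30
    frac_glycolytic: float = 0.35
    state_correlation: float = 0.6
    program_size: int = 40
    effect_size: float = 2.0
    dispersion: float = 10.0
    lib_size_mean: float = 8000.0
    lib_size_sigma: float = 0.3
    n_clusters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_genes < 2:
            raise ConfigError("n_cells and n_genes must be at least 2")
        for name in ("frac_malignant", "frac_hybrid", "frac_mesenchymal",
                     "frac_stem", "frac_glycolytic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_hybrid + self.frac_mesenchymal > 1.0:
            raise ConfigError("frac_hybrid + frac_mesenchymal must not exceed 1")
        if not 0.0 <= self.state_correlation < 1.0:
            raise ConfigError("state_correlation must lie in [0, 1)")
        if self.program_size < 5:
            raise ConfigError("program_size must be at least 5")
        if self.n_genes < len(PROGRAM_NAMES) * self.program_size:
            raise ConfigError(
                f"n_genes={self.n_genes} cannot hold {len(PROGRAM_NAMES)} disjoint "
                f"programs of {self.program_size} genes"
            )
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.lib_size_mean <= 0 or self.lib_size_sigma < 0:
            raise ConfigError("library-size parameters must be positive")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted per-cell state labels and program gene lists."""

    cells: pd.DataFrame  # cell_id, malignant, emt_state, stem, metabolic_state, cluster, aggressive
    programs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"cell_id", "malignant", "emt_state", "stem",
                    "metabolic_state", "cluster", "aggressive"}
        missing = required - set(self.cells.columns)
        if missing:
            raise DataError(f"ground-truth table missing columns {sorted(missing)}")

    @property
    def aggressive_marker_genes(self) -> list[str]:
        """Genes of the programs whose joint carriers define the
        aggressive flag (EMT drivers + stemness + glycolysis)."""
        return (
            self.programs["emt_drivers"]
            + self.programs["stemness"]
            + self.programs["glycolysis"]
        )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth, GeneSetCollection]:
    """Generate counts, ground truth and the planted signature collection.

    All randomness flows through one ``numpy.random.default_rng`` stream
    seeded from ``config.seed``, so identical configs give bit-identical
    outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, g, ps = cfg.n_cells, cfg.n_genes, cfg.program_size

    gene_ids = [f"G{i:05d}" for i in range(g)]
    cell_ids = [f"C{i:05d}" for i in range(n)]

    programs: dict[str, list[int]] = {}
    for pi, name in enumerate(PROGRAM_NAMES):
        programs[name] = list(range(pi * ps, (pi + 1) * ps))
    n_program_genes = len(PROGRAM_NAMES) * ps
    leftover = g - n_program_genes
    block = min(ps, leftover // cfg.n_clusters) if cfg.n_clusters else 0
    cluster_blocks = [
        list(range(n_program_genes + c * block, n_program_genes + (c + 1) * block))
        for c in range(cfg.n_clusters)
    ]

    # per-cell states; hybrid/stem/glycolytic flags share a Gaussian
    # copula latent so the aggressive phenotype is a coherent axis while
    # each flag keeps its marginal fraction
    malignant = rng.random(n) < cfg.frac_malignant
    rho = cfg.state_correlation
    z0 = rng.normal(size=n)
    z = rho * z0[:, None] + np.sqrt(1.0 - rho ** 2) * rng.normal(size=(n, 3))
    p_latent = scipy.stats.norm.cdf(z)
    hybrid = p_latent[:, 0] < cfg.frac_hybrid
    stem = p_latent[:, 1] < cfg.frac_stem
    glyc = p_latent[:, 2] < cfg.frac_glycolytic
    emt_state = np.full(n, "epithelial", dtype=object)
    if cfg.frac_hybrid < 1.0:
        p_mes = cfg.frac_mesenchymal / (1.0 - cfg.frac_hybrid)
        emt_state[~hybrid & (rng.random(n) < p_mes)] = "mesenchymal"
    emt_state[hybrid] = "hybrid"
    cluster = rng.integers(0, cfg.n_clusters, size=n)
    # non-malignant cells stay in the neutral state
    emt_state[~malignant] = "epithelial"
    stem[~malignant] = False
    glyc[~malignant] = False

    log_base = rng.normal(0.0, 1.0, size=g)
    log_rate = np.tile(log_base, (n, 1))
    eff = cfg.effect_size

    def activate(cell_mask: np.ndarray, gene_idx: list[int], effect: float) -> None:
        if effect != 0 and cell_mask.any() and gene_idx:
            log_rate[np.ix_(cell_mask, gene_idx)] += effect

    is_epi = malignant & (emt_state == "epithelial")
    is_mes = malignant & (emt_state == "mesenchymal")
    is_hyb = malignant & (emt_state == "hybrid")
    activate(is_epi, programs["epithelial"], eff)
    activate(is_mes, programs["mesenchymal"], eff)
    activate(is_mes, programs["emt_drivers"], eff)
    activate(is_hyb, programs["epithelial"], eff / 2.0)
    activate(is_hyb, programs["mesenchymal"], eff / 2.0)
    activate(is_hyb, programs["emt_drivers"], eff)
    activate(malignant & stem, programs["stemness"], eff)
    activate(malignant & glyc, programs["glycolysis"], eff)
    activate(malignant & ~glyc, programs["oxphos"], eff)
    activate(malignant, programs["malignant"], eff)
    for c in range(cfg.n_clusters):
        activate(cluster == c, cluster_blocks[c], eff)

    rate = np.exp(log_rate)
    prob = rate / rate.sum(axis=1, keepdims=True)
    lib = rng.lognormal(
        mean=np.log(cfg.lib_size_mean) - cfg.lib_size_sigma ** 2 / 2.0,
        sigma=cfg.lib_size_sigma,
        size=n,
    )
    mu = lib[:, None] * prob
    lam = rng.gamma(shape=cfg.dispersion, scale=mu / cfg.dispersion)
    counts = rng.poisson(lam).astype(np.float64)

    matrix = ExpressionMatrix(counts, cell_ids, gene_ids, layer="counts")
    truth = GroundTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "malignant": malignant,
                "emt_state": emt_state.astype(str),
                "stem": stem,
                "metabolic_state": np.where(glyc, "glycolytic", "oxidative"),
                "cluster": cluster,
                "aggressive": malignant & (emt_state == "hybrid") & stem & glyc,
            }
        ),
        programs={
            name: [gene_ids[i] for i in idx] for name, idx in programs.items()
        },
    )
    signatures = GeneSetCollection(
        {name: list(genes) for name, genes in truth.programs.items()}
    )
    return matrix, truth, signatures


def truth_roc(score: np.ndarray, label: np.ndarray) -> float:
    """AUROC of ``score`` against boolean ``label``.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg, with
    ties counted one half (midranks).
    """
    score = np.asarray(score, dtype=np.float64)
    label = np.asarray(label, dtype=bool)
    if score.shape != label.shape:
        raise DataError("score and label vectors differ in length")
    n_pos = int(label.sum())
    n_neg = int((~label).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUROC undefined: labels contain a single class")
    ranks = scipy.stats.rankdata(score)
    u = ranks[label].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def write_dataset(
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    signatures: GeneSetCollection,
    out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> None:
    """Write matrix.mtx + barcodes.tsv + features.tsv, truth.tsv,
    signatures.gmt and (optionally) the generating config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_market(matrix, out)
    truth.cells.to_csv(out / "truth.tsv", sep="\t", index=False)
    write_gmt(signatures, out / "signatures.gmt")
    if config is not None:
        (out / "sim_config.yaml").write_text(yaml.safe_dump(config.to_dict()))


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("malignant", "stem", "aggressive"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
        df[col] = df[col].astype(bool)
    return df
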