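import numpy as np
import pytest

from metascore.io import ExpressionMatrix


def make_matrix(x, layer="lognorm", cell_prefix="c", gene_prefix="g"):
    x = np.asarray(x, dtype=float)
    return ExpressionMatrix(
        x,
        [f"{cell_prefix}{i}" for i in range(x.shape[0])],
        [f"{gene_prefix}{j}" for j in range(x.shape[1])],
        layer=layer,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_lognorm(rng):
    """50 cells x 100 genes with distinct per-gene means."""
    x = rng.gamma(2.0, 0.5, size=(50, 100))
    x += np.linspace(0.0, 3.0, 100)[None, :]  # spread the gene means
    return make_matrix(x, layer="lognorm")
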