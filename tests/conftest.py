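import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from panelscope.matrix import NORMALIZED_FLAG, make_labeled

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def labeled(counts, subsets, genes=None, samples=None):
    """Small labeled AnnData from a dense count array."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = genes if genes is not None else [f"G{j}" for j in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    return make_labeled(counts, genes, cells, subsets, samples)


def normalized(values, subsets, genes=None):
    """Labeled AnnData whose X is a pre-set normalized layer (for OER tests)."""
    values = np.asarray(values, dtype=float)
    adata = labeled(np.zeros(values.shape, dtype=int), subsets, genes)
    adata.layers["counts"] = adata.X
    adata.X = values
    adata.uns[NORMALIZED_FLAG] = True
    return adata


@pytest.fixture
def gmt_writer(tmp_path):
    def write(rows, name="panels.gmt"):
        path = tmp_path / name
        path.write_text("\n".join("\t".join(r) for r in rows) + "\n", encoding="utf-8")
        return path

    return write
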