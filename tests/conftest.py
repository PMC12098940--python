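import anndata
import numpy as np
import pandas as pd
import pytest


def make_bundle(
    n_cells=20,
    n_genes=5,
    seed=0,
    gene_names=None,
    with_layers=False,
    integer_counts=False,
):
    """Small dense fixture bundle with per-cell annotations."""
    rng = np.random.default_rng(seed)
    if integer_counts:
        X = rng.integers(0, 20, size=(n_cells, n_genes)).astype(np.float32)
    else:
        X = rng.random((n_cells, n_genes), dtype=np.float32) * 10
    obs = pd.DataFrame(
        {"celltype": [f"t{i % 3}" for i in range(n_cells)]},
        index=[f"c{i}" for i in range(n_cells)],
    )
    bundle = anndata.AnnData(X=X, obs=obs)
    bundle.var_names = (
        gene_names if gene_names is not None else [f"g{j}" for j in range(n_genes)]
    )
    if with_layers:
        from scipy import sparse

        bundle.var["chrom"] = [str(j % 4) for j in range(n_genes)]
        bundle.obsm["X_pca"] = rng.random((n_cells, 3))
        bundle.varm["loadings"] = rng.random((n_genes, 2))
        bundle.obsp["connectivity"] = sparse.random(
            n_cells, n_cells, density=0.1, random_state=seed, format="csr"
        )
        bundle.uns["note"] = "qc-pass"
        bundle.uns["params"] = {"k": 5, "resolution": 0.8}
        bundle.uns["grid"] = np.arange(4, dtype=np.int64).reshape(2, 2)
    return bundle


@pytest.fixture
def small_bundle():
    return make_bundle()


@pytest.fixture
def layered_bundle():
    return make_bundle(n_cells=30, n_genes=8, seed=1, with_layers=True)


def deep_equal(a, b) -> bool:
    """Structural equality across mappings, sequences, arrays and scalars,
    preserving array dtype/shape and list-vs-tuple kind."""
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return (
            isinstance(a, np.ndarray)
            and isinstance(b, np.ndarray)
            and a.dtype == b.dtype
            and a.shape == b.shape
            and np.array_equal(a, b)
        )
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(deep_equal(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return (
            type(a) is type(b)
            and len(a) == len(b)
            and all(deep_equal(x, y) for x, y in zip(a, b))
        )
    return type(a) is type(b) and a == b
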