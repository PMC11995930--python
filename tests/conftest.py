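import anndata as ad
import numpy as np
import pandas as pd
import pytest

from atlaswalk import GeneratorConfig, make_reference_atlas, simulate_cells


def make_adata(X, cells=None, genes=None) -> ad.AnnData:
    """Dense array (cells x genes) -> AnnData with readable identifiers."""
    X = np.asarray(X)
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    genes = genes or [f"g{j}" for j in range(X.shape[1])]
    return ad.AnnData(
        X=X.astype(float),
        obs=pd.DataFrame(index=pd.Index(cells, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        seed=42, n_types=3, n_genes=80, n_cells_per_type=60,
        n_marker_genes_per_type=8, mito_gene_count=6,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    return make_reference_atlas(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_atlas):
    return simulate_cells(small_atlas, small_config)
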