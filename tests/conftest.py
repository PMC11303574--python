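import numpy as np
import pandas as pd
import pytest

import mave_evidence as me
from mave_evidence.config import ModelingConfig, SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A desk-scale experiment: 16 variants x 25 cells, 200 genes."""
    return SimulationConfig(
        n_variants=16,
        n_cells_per_variant=25,
        n_genes=200,
        n_module_genes=25,
        n_mito_genes=5,
        coding_length=300,
        long_read_depth=40,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return me.generate_manifest(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_manifest):
    return me.generate_truth(small_manifest, small_config)


@pytest.fixture(scope="session")
def small_adata(small_config, small_truth):
    return me.simulate_expression(small_truth, small_config)


@pytest.fixture(scope="session")
def truth_assignments(small_truth) -> pd.DataFrame:
    """Ground-truth cell-to-variant table in the assignments schema."""
    return pd.DataFrame(
        {
            "cell_barcode": small_truth.cells,
            "variant_id": [small_truth.cell_to_variant[c] for c in small_truth.cells],
        }
    )


@pytest.fixture(scope="session")
def fast_modeling_config() -> ModelingConfig:
    return ModelingConfig(n_features=60, n_pcs=6, seed=7)
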