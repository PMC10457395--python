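import numpy as np
import pandas as pd
import pytest

from mixproject import simulate
from mixproject.datatypes import CellAtlas, ExpressionMatrix
from mixproject.pipeline import prepare_inputs
from mixproject.vae import VAEConfig, train_atlas_vaes


def subset_cells(atlas: CellAtlas, cols: list[int]) -> CellAtlas:
    expr = ExpressionMatrix(
        atlas.expr.values[:, cols],
        list(atlas.expr.gene_ids),
        [atlas.expr.obs_ids[i] for i in cols],
        atlas.expr.layer_tag,
    )
    return CellAtlas(expr=expr, cell_types=[atlas.cell_types[i] for i in cols])


@pytest.fixture(scope="session")
def toy_problem():
    """Small 2-type problem shared across model tests.

    Atlas is split into train/held-out cells; mixtures are 2-type summed
    pseudo-bulk samples with known contributors.
    """
    atlas_counts = simulate.make_atlas(2, 60, 120, separation=0.4, seed=42)
    mixtures_counts, truth = simulate.make_mixture_sets(atlas_counts, [2], 60, seed=43)
    ann = pd.Series(atlas_counts.cell_types, index=atlas_counts.expr.obs_ids)
    atlas, mixtures = prepare_inputs(atlas_counts.expr, ann, mixtures_counts.expr)

    train_cols, held_cols = [], []
    for lab in atlas.labels:
        cells = atlas.cells_of_type(lab)
        train_cols.extend(cells[:100])
        held_cols.extend(cells[100:])
    return {
        "atlas": atlas,
        "train_atlas": subset_cells(atlas, train_cols),
        "heldout_atlas": subset_cells(atlas, held_cols),
        "mixtures": mixtures,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def toy_config():
    return VAEConfig(
        latent_dim=6, hidden=(32, 16), epochs=60, dropout=0.1,
        learning_rate=3e-3, seed=0,
    )


@pytest.fixture(scope="session")
def toy_bundle(toy_problem, toy_config):
    return train_atlas_vaes(
        toy_problem["train_atlas"], toy_config, panel=toy_problem["mixtures"].panel
    )
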