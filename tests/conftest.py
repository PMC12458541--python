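import numpy as np
import pytest

import zipaer as z
from zipaer.patchify import PatchConfig, densify_all


@pytest.fixture(scope="session")
def default_sim():
    """Default desk-scale simulation: 1 FOV of 2000 px, 50 cells, 100 genes."""
    cfg = z.SimConfig()
    transcripts, cells, truth = z.simulate(cfg)
    return cfg, transcripts, cells, truth


@pytest.fixture(scope="session")
def vocab(default_sim):
    _, _, _, truth = default_sim
    return z.GeneVocabulary(list(truth.gene_means["gene"]))


@pytest.fixture(scope="session")
def patch_stack(default_sim, vocab):
    """Dense 64-px / r=2 patches for every simulated cell, with labels."""
    _, transcripts, cells, truth = default_sim
    records = z.assign_transcripts_to_patches(transcripts, cells, 64, vocab)
    store = z.SparsePatchStore(records)
    config = PatchConfig(patch_size_px=64, reduction_r=2)
    stack, ids = densify_all(store, config, vocab)
    labels = (
        truth.cell_labels.set_index("cell_id").loc[ids, "label"].to_numpy()
    )
    return stack, ids, labels, config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
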