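import numpy as np
import pytest

import eigencell as ec


@pytest.fixture(scope="session")
def flat_dataset():
    """Three well-separated classes, small enough for fast training."""
    cfg = ec.SimulationConfig(
        n_cells_per_class=80,
        n_genes=600,
        n_effect_genes=60,
        effect_size=1.0,
        class_names=("alpha", "beta", "delta"),
        seed=11,
    )
    return ec.generate_class_counts(cfg)


@pytest.fixture(scope="session")
def trained_bundle(flat_dataset):
    cfg = ec.PipelineConfig(folds=5, seed=11)
    return ec.train_model(flat_dataset.counts, flat_dataset.labels, cfg)


@pytest.fixture(scope="session")
def hier_dataset():
    cfg = ec.SimulationConfig(
        n_cells_per_class=60,
        n_genes=600,
        n_effect_genes=40,
        effect_size=1.2,
        hierarchy={"lymphoid": {"T": {}, "B": {}}, "myeloid": {}},
        seed=7,
    )
    return ec.generate_hierarchical_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
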