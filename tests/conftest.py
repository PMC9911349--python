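import numpy as np
import pytest

from lncexport import synthetic
from lncexport.pipeline import default_u1_model


@pytest.fixture(scope="session")
def u1_model():
    """Donor/U1 maxent model trained on noisy consensus sites."""
    return default_u1_model(seed=0)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort shared by read-only tests."""
    cfg = synthetic.SimConfig(n_genes=60, seed=11)
    sequences, models, truth = synthetic.simulate_genome(cfg)
    counts, junctions, fulllength = synthetic.simulate_fraction_counts(models, truth, cfg)
    return {
        "config": cfg,
        "sequences": sequences,
        "models": models,
        "truth": truth,
        "counts": counts,
        "junctions": junctions,
        "fulllength": fulllength,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
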