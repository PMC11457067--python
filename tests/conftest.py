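import numpy as np
import pytest
from hypothesis import settings

import gxepred as gp

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_data():
    """40 genotypes x 200 markers x 4 sites: seconds-scale end-to-end data."""
    cfg = gp.make_config("tiny", seed=1)
    dosage, meta, G, table, truth = gp.simulate_dataset(cfg)
    return dict(config=cfg, dosage=dosage, meta=meta, G=G, table=table,
                truth=truth, agg=gp.aggregate_phenotypes(table))


@pytest.fixture(scope="session")
def small_data():
    """300 genotypes x 2000 markers x 10 sites with the replication profile."""
    cfg = gp.make_config("small", seed=5)
    dosage, meta, G, table, truth = gp.simulate_dataset(cfg)
    return dict(config=cfg, dosage=dosage, meta=meta, G=G, table=table,
                truth=truth, agg=gp.aggregate_phenotypes(table))


def random_grm(rng, n, n_markers=400):
    """Well-conditioned kinship-like matrix for model unit tests."""
    a = rng.standard_normal((n, n_markers))
    g = a @ a.T / n_markers
    g /= np.diag(g).mean()
    return (g + g.T) / 2.0
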