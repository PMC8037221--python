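import numpy as np
import pandas as pd
import pytest

import icbbench as ib


@pytest.fixture(scope="session")
def registry():
    return ib.load_signature_definitions()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_expr(rng):
    """10 genes x 6 samples of positive log-expression."""
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{j}" for j in range(6)]
    vals = rng.uniform(0.5, 8.0, size=(10, 6))
    return pd.DataFrame(vals, index=genes, columns=samples)


@pytest.fixture(scope="session")
def planted_cohort(registry):
    """Small multi-dataset cohort with a planted CYT effect."""
    cfg = ib.SimConfig(
        seed=11,
        n_genes=60,
        planted_signatures=[ib.PlantedSignature("CYT", 1.0)],
        datasets=[
            ib.DatasetConfig("dsA", 50),
            ib.DatasetConfig("dsB", 40, cancer_type="UC", therapy="anti_pdl1"),
        ],
    )
    return ib.simulate_cohort(cfg, registry)
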