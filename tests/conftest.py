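import warnings

import numpy as np
import pandas as pd
import pytest

import scdeltact as sd

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_ct():
    """3 samples x 4 assays, one non-detect, two batches."""
    values = pd.DataFrame(
        {
            "Tnf": [25.0, 26.0, 24.5],
            "cFos": [27.0, np.nan, 26.5],
            "Ldha": [20.0, 20.5, 19.5],
            "Actb": [22.0, 21.5, 22.5],
        },
        index=["s1", "s2", "s3"],
    )
    return sd.CtMatrix(values)


@pytest.fixture
def tiny_meta():
    return pd.DataFrame(
        {
            "animal_id": ["a1", "a1", "a2"],
            "treatment": ["Placebo", "Placebo", "Withdrawal"],
            "cell_type": ["neuron"] * 3,
            "batch_id": ["b1", "b1", "b2"],
            "pool_size": [10] * 3,
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )


@pytest.fixture(scope="session")
def brain_sim():
    """One modest synthetic brain dataset shared across read-only tests."""
    cfg = sd.default_brain_config(seed=11, n_pools_per_animal=6)
    ct, meta, truth = sd.generate_sc_qpcr(cfg)
    return cfg, ct, meta, truth


@pytest.fixture(scope="session")
def brain_expression(brain_sim):
    cfg, ct, meta, truth = brain_sim
    expr, dropped = sd.normalize(ct, ["Ldha", "Actb"], scope="global")
    meta = meta.loc[expr.values.index]
    return expr, meta, truth
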