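import pandas as pd
import pytest

from rhizometab import (
    SimConfig,
    generate_index_table,
    generate_metabolome,
    make_sample_meta,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_metabolites=120, n_pos=20, n_neg=30, missing_rate=0.1)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    matrix, annotations, truth = generate_metabolome(small_cfg)
    return {
        "cfg": small_cfg,
        "matrix": matrix,
        "annotations": annotations,
        "truth": truth,
        "meta": make_sample_meta(small_cfg),
        "indexes": generate_index_table(small_cfg),
    }


@pytest.fixture(scope="session")
def planted_cfg():
    # only planted features, essentially noiseless: ideal recovery conditions
    return SimConfig(
        seed=3, n_metabolites=221, n_pos=55, n_neg=166, noise_sd=1e-3, missing_rate=0.0
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_cfg):
    matrix, annotations, truth = generate_metabolome(planted_cfg)
    return {
        "cfg": planted_cfg,
        "matrix": matrix,
        "annotations": annotations,
        "truth": truth,
        "meta": make_sample_meta(planted_cfg),
        "indexes": generate_index_table(planted_cfg),
    }


@pytest.fixture
def toy_meta():
    meta = pd.DataFrame(
        {
            "sample_id": [f"{g}_{r}" for g in ("P1", "P2", "P3") for r in (1, 2, 3)],
            "group_id": [g for g in ("P1", "P2", "P3") for _ in range(3)],
            "replicate": [1, 2, 3] * 3,
        }
    )
    meta["group_id"] = pd.Categorical(meta["group_id"], categories=["P1", "P2", "P3"], ordered=True)
    return meta
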