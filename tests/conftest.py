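import numpy as np
import pytest

import quadnet as q


@pytest.fixture(scope="session")
def small_spec():
    return q.SyntheticSpec(
        n_proteins=300, dim=16, tail_df=3.0, rule_rank=4,
        label_noise=0.0, pos_frac=0.5, seed=42,
    )


@pytest.fixture(scope="session")
def small_store(small_spec):
    return q.generate_protein_embeddings(small_spec)


@pytest.fixture(scope="session")
def small_oracle(small_spec, small_store):
    return q.plant_interaction_rule(small_store, small_spec)


@pytest.fixture(scope="session")
def small_pairs(small_spec, small_store, small_oracle):
    return q.sample_pair_dataset(small_store, small_oracle, 4000, seed=small_spec.seed)


@pytest.fixture(scope="session")
def small_scaler(small_store):
    return q.fit_robust_scaler(small_store.matrix)


@pytest.fixture
def tiny_model_cfg():
    return q.ModelConfig(
        input_dim=8, hidden_dim=16, num_heads=2, n_tokens=4, dropout=0.0, seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
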