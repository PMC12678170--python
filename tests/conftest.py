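import numpy as np
import pytest

from flowcfr.model import CondFlow, ModelData, TrainConfig, train_model
from flowcfr.simulate import SimConfig, generate_cohort


def randomized_flow(cond_dim, n_blocks=3, cond_hidden=8, seed=0, scale=0.4):
    """A CondFlow with randomized (non-identity) parameters."""
    rng = np.random.default_rng(seed)
    fl = CondFlow(cond_dim, n_blocks, cond_hidden, rng)
    for k in fl.params:
        fl.params[k] = fl.params[k] + rng.normal(0.0, scale, np.shape(fl.params[k]))
    return fl


TINY_TRAIN = TrainConfig(
    seed=0,
    enc_hidden=(16,),
    head_hidden=8,
    batch_size=64,
    stage0_epochs=20,
    patience=8,
    flow_epochs=40,
    flow_patience=8,
)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_encounters=400, d_measured=6, gamma_hidden=0.5,
                    tau_fn_id="sign_flipping", tau_scale=0.12, base_rate=0.25,
                    ts_hours=30, missing_rate=0.3, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_data(small_cohort):
    return ModelData(
        X=small_cohort.x,
        a=small_cohort.frame["a"].to_numpy(),
        y=small_cohort.frame["y"].to_numpy(),
    )


@pytest.fixture(scope="session")
def tiny_model(small_data):
    return train_model(small_data, TINY_TRAIN)
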