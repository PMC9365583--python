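import numpy as np
import pytest

import lodoct as L

TINY_CFG = dict(
    stem_channels=8,
    growth_channels=8,
    dense_layers_per_block=2,
    bottleneck_channels=16,
    n_levels=2,
    decoder_channels=16,
)

# Scaled-down study conditions for the end-to-end run: 40 training pairs at
# 10% dose, 8 held-out, 5 pretraining + 10 mechanism epochs, default loss
# weights, 3 MS-SSIM scales (64-px images), lr 1e-3 halving at mechanism
# epoch 8.
E2E = dict(
    n_train=40,
    n_val=8,
    phantom_seed=100,
    noise_seed=200,
    model_seed=1,
    run_seed=1,
)


def tiny_network_config(**overrides):
    return L.NetworkConfig(**{**TINY_CFG, **overrides})


def scaled_down_run_config():
    return L.RunConfig(
        network=tiny_network_config(),
        ms_ssim=L.MsSsimParams(n_scales=3),
        mechanism=L.MechanismConfig(threshold=0.04, pretrain_epochs=5, mechanism_epochs=10),
        trainer=L.TrainConfig(
            batch_size=8, learning_rate=1e-3, lr_after_drop=5e-4, lr_drop_epoch=8
        ),
        seed=E2E["run_seed"],
    )


def simulate_dataset(n_pairs, phantom_seed, noise_seed, **sim_overrides):
    pairs = []
    for i in range(n_pairs):
        spec = L.PhantomSpec(seed=phantom_seed + i)
        cfg = L.SimConfig(seed=noise_seed + i, **sim_overrides)
        pairs.append(L.simulate_pair(L.generate_phantom(spec), cfg))
    return pairs


def run_scaled_down_training():
    """One deterministic scaled-down training run; returns model, log, data."""
    pairs = simulate_dataset(
        E2E["n_train"] + E2E["n_val"], E2E["phantom_seed"], E2E["noise_seed"]
    )
    train_set, val_set = pairs[: E2E["n_train"]], pairs[E2E["n_train"] :]
    run_cfg = scaled_down_run_config()
    model = L.build_model(run_cfg.network, seed=E2E["model_seed"])
    model, log = L.train(model, train_set, run_cfg)
    return model, log, train_set, val_set


@pytest.fixture(scope="session")
def random_pairs_64():
    """20 seeded random 64x64 image pairs in [0, 1]."""
    out = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        out.append((rng.uniform(0, 1, (64, 64)), rng.uniform(0, 1, (64, 64))))
    return out


@pytest.fixture(scope="session")
def tiny_model():
    return L.build_model(tiny_network_config(), seed=7).eval()


@pytest.fixture(scope="session")
def sim_pair():
    return L.simulate_pair(
        L.generate_phantom(L.PhantomSpec(seed=11)), L.SimConfig(seed=11)
    )


@pytest.fixture(scope="session")
def trained_run():
    """The scaled-down end-to-end training run, shared across tests."""
    return run_scaled_down_training()
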