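import numpy as np
import pytest

import litepath as lp


@pytest.fixture(scope="session")
def tiny_sets():
    """Very small 16x16 synthetic splits for fast trainer-level tests."""
    cfg = lp.SynthConfig(n_per_class=12, image_size=16, separability=0.9, seed=7)
    return lp.generate_dataset(cfg, n_val_per_class=6, n_test_per_class=6)


@pytest.fixture(scope="session")
def small_image_set():
    cfg = lp.SynthConfig(n_per_class=5, image_size=32, separability=0.9, seed=1)
    return lp.generate_split(cfg, split_tag="train")


@pytest.fixture(scope="session")
def benchmark_run():
    """The scaled-down reference experiment: Lite-V0 on 64x64 synthetic data,
    200/60/60 images per class, separability 0.9, seed 42, at most 15 epochs.

    Shared session-wide because training takes on the order of a minute.
    Returns (run_log, test_eval, train_set)."""
    cfg = lp.SynthConfig(n_per_class=200, image_size=64, separability=0.9, seed=42)
    train_set, val_set, test_set = lp.generate_dataset(cfg, 60, 60)
    train_cfg = lp.TrainConfig(seed=42, max_epochs=15, patience=6)
    _, model = lp.build_model(lp.builtin_variants(64)["Lite-V0"], seed=42)
    run_log = lp.train_variant(model, train_set, val_set, train_cfg)
    test_eval = lp.evaluate_model(model, test_set)
    return run_log, test_eval, train_set


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
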