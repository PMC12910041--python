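import math

import numpy as np
import pytest

import litepath as lp
from litepath.synthgen import ConfigurationError

TINY_CFG = lp.VariantConfig(name="tiny", filters=(8, 16), input_size=16)


class TestWeightedCrossEntropy:
    def test_uniform_probabilities_give_ln3(self):
        p = np.full((10, 3), 1 / 3)
        y = np.arange(10) % 3
        assert lp.weighted_cross_entropy(p, y) == pytest.approx(math.log(3))

    def test_one_hot_correct_predictions_give_zero(self):
        y = np.array([0, 1, 2])
        p = np.eye(3)[y]
        assert lp.weighted_cross_entropy(p, y) == pytest.approx(0.0, abs=1e-10)

    def test_class_weight_scales_sample_loss(self):
        p = np.array([[0.5, 0.25, 0.25]])
        y = np.array([0])
        table = lp.ClassWeightTable(weights={0: 2.0, 1: 1.0, 2: 1.0})
        assert lp.weighted_cross_entropy(p, y, table) == pytest.approx(
            2 * -math.log(0.5)
        )  # 1.3863

    def test_rejects_unnormalized_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            lp.weighted_cross_entropy(np.array([[0.5, 0.2, 0.2]]), np.array([0]))

    def test_zero_probability_clamped(self):
        p = np.array([[1.0, 0.0, 0.0]])
        loss = lp.weighted_cross_entropy(p, np.array([1]))
        assert np.isfinite(loss) and loss == pytest.approx(-math.log(1e-12))


class TestSelectBestEpoch:
    def test_strictly_increasing_never_stops(self):
        history = [0.1 * k for k in range(1, 11)]
        best, stop = lp.select_best_epoch(history, patience=6, tolerance=1e-4)
        assert (best, stop) == (10, 10)

    def test_hand_traced_plateau(self):
        history = [0.50, 0.90, 0.89, 0.89, 0.89, 0.89, 0.89, 0.89]
        best, stop = lp.select_best_epoch(history, patience=6, tolerance=1e-4)
        assert (best, stop) == (2, 8)

    def test_late_maximum_selected(self):
        # peak at epoch 24 of a 25-epoch run
        history = [0.5 + 0.015 * k for k in range(24)] + [0.6]
        assert max(history) == history[23]
        best, stop = lp.select_best_epoch(history, patience=6, tolerance=1e-4)
        assert best == 24

    def test_improvement_must_exceed_tolerance(self):
        # +tolerance exactly is NOT an improvement (strict rule)
        history = [0.5, 0.5 + 1e-4, 0.5, 0.5, 0.5]
        best, stop = lp.select_best_epoch(history, patience=3, tolerance=1e-4)
        assert best == 1
        assert stop == 4

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            lp.select_best_epoch([], patience=6, tolerance=1e-4)


class TestTrainConfig:
    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ConfigurationError, match="patience"):
            lp.TrainConfig(max_epochs=5, patience=6)

    def test_defaults_match_protocol(self):
        cfg = lp.TrainConfig()
        assert cfg.learning_rate == pytest.approx(1e-3)
        assert cfg.batch_size == 32
        assert cfg.max_epochs == 25
        assert cfg.patience == 6
        assert cfg.improvement_tolerance == pytest.approx(1e-4)
        assert cfg.seed == 42
        assert cfg.use_class_weights is True
        assert cfg.reduce_lr_on_plateau is False


@pytest.fixture(scope="module")
def trained(tiny_sets):
    train_set, val_set, test_set = tiny_sets
    cfg = lp.TrainConfig(seed=11, max_epochs=4, patience=2, batch_size=8)
    _, model = lp.build_model(TINY_CFG, seed=11)
    log = lp.train_variant(model, train_set, val_set, cfg, augment=None)
    return model, log, val_set


class TestTrainVariant:
    def test_history_bounded_by_max_epochs(self, trained):
        _, log, _ = trained
        assert len(log.records) <= 4
        assert [r.epoch for r in log.records] == list(
            range(1, len(log.records) + 1)
        )

    def test_runlog_invariants(self, trained):
        _, log, _ = trained
        f1s = log.history("val_macro_f1")
        assert log.best_val_macro_f1 == pytest.approx(max(f1s))
        assert log.best_epoch == int(np.argmax(f1s)) + 1  # first argmax
        if log.stopped_early:
            assert log.records[-1].epoch == log.best_epoch + log.config.patience

    def test_checkpoint_fidelity(self, trained):
        """Metrics recomputed from the restored best checkpoint equal the
        logged best validation macro-F1."""
        model, log, val_set = trained
        recomputed = lp.evaluate_model(model, val_set).macro_f1
        assert recomputed == pytest.approx(log.best_val_macro_f1, abs=1e-6)

    def test_empty_validation_rejected(self, tiny_sets):
        train_set, _, _ = tiny_sets
        empty = lp.LabeledImageSet(
            images=np.zeros((0, 16, 16, 3), dtype=np.float32),
            labels=np.zeros(0, dtype=np.int64),
            class_names=train_set.class_names,
        )
        _, model = lp.build_model(TINY_CFG, seed=0)
        with pytest.raises(ConfigurationError, match="alidation"):
            lp.train_variant(model, train_set, empty, lp.TrainConfig())

    def test_seed_determinism_epoch1_loss(self, tiny_sets):
        train_set, val_set, _ = tiny_sets
        cfg = lp.TrainConfig(seed=3, max_epochs=2, patience=1, batch_size=8)
        losses = []
        for _ in range(2):
            _, model = lp.build_model(TINY_CFG, seed=3)
            log = lp.train_variant(model, train_set, val_set, cfg, augment=None)
            losses.append(log.records[0].train_loss)
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_plateau_stops_at_best_plus_patience(self, tiny_sets, monkeypatch):
        """Inject a scripted macro-F1 stream: training must halt exactly at
        best_epoch + patience."""
        train_set, val_set, _ = tiny_sets
        scripted = iter([0.50, 0.90, 0.89, 0.88, 0.87, 0.86, 0.85, 0.84, 0.95])
        import litepath.trainer as trainer_mod

        real_eval = trainer_mod.evaluate_model

        def stubbed_eval(model, image_set, batch_size=64):
            result = real_eval(model, image_set, batch_size=batch_size)
            try:
                forced = next(scripted)
            except StopIteration:
                return result
            object.__setattr__(result, "macro_f1", forced)
            return result

        monkeypatch.setattr(trainer_mod, "evaluate_model", stubbed_eval)
        cfg = lp.TrainConfig(seed=5, max_epochs=20, patience=6, batch_size=8)
        _, model = lp.build_model(TINY_CFG, seed=5)
        log = trainer_mod.train_variant(model, train_set, val_set, cfg, augment=None)
        assert log.stopped_early
        assert log.best_epoch == 2
        assert log.records[-1].epoch == 8


class TestRunStability:
    def test_requires_two_seeds(self, tiny_sets):
        with pytest.raises(ValueError, match="2 seeds"):
            lp.run_stability(TINY_CFG, tiny_sets, lp.TrainConfig(), seeds=[1])

    def test_two_seed_summary_shape(self, tiny_sets):
        cfg = lp.TrainConfig(seed=0, max_epochs=2, patience=1, batch_size=8)
        summary, logs = lp.run_stability(
            TINY_CFG, tiny_sets, cfg, seeds=[1, 2], augment=None
        )
        assert summary.n_runs == 2 and len(logs) == 2
        assert {log.config.seed for log in logs} == {1, 2}
        for metric in ("val_accuracy", "val_macro_f1", "test_accuracy", "test_macro_f1"):
            m = summary.metrics[metric]
            assert 0.0 <= m["mean"] <= 1.0 and m["sd"] >= 0.0


class TestCompareVariants:
    def test_ranking_and_single_test_evaluation(self, tiny_sets):
        variants = {
            "tiny-a": TINY_CFG,
            "tiny-b": lp.VariantConfig(name="tiny-b", filters=(4, 8), input_size=16),
        }
        cfg = lp.TrainConfig(seed=2, max_epochs=2, patience=1, batch_size=8)
        result = lp.compare_variants(variants, tiny_sets, cfg, augment=None)
        assert set(result["ranking"]) == set(variants)
        assert result["winner"] == result["ranking"][0]
        bests = {n: result["logs"][n].best_val_macro_f1 for n in variants}
        assert bests[result["ranking"][0]] >= bests[result["ranking"][1]] - 1e-12
        assert 0.0 <= result["test_eval"].macro_f1 <= 1.0

    def test_tie_goes_to_smaller_model(self, tiny_sets, monkeypatch):
        import litepath.trainer as trainer_mod

        def fake_train(model, train_set, val_set, cfg, augment=None, **kw):
            return lp.RunLog(
                variant=model.config.name, config=cfg,
                records=[lp.trainer.EpochRecord(1, 0.5, 0.5, 0.5, 0.5, 0.9)],
                best_epoch=1, best_val_macro_f1=0.9,
                checkpoint_path="", stopped_early=False,
            )

        monkeypatch.setattr(trainer_mod, "train_variant", fake_train)
        big = lp.VariantConfig(name="big", filters=(16, 32), input_size=16)
        small = lp.VariantConfig(name="small", filters=(4, 8), input_size=16)
        result = trainer_mod.compare_variants(
            {"big": big, "small": small},
            tiny_sets,
            lp.TrainConfig(max_epochs=2, patience=1),
        )
        assert result["winner"] == "small"
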