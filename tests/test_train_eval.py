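"""Training loop: history, monitoring, loss switch, early stopping, search."""

import numpy as np
import pytest

import dtikit
from dtikit import train_eval
from dtikit.train_eval import TrainConfig, _xy

from conftest import TINY, tiny_model


def tiny_cfg(**kw):
    kw.setdefault("epochs", 1)
    kw.setdefault("batch_size", 8)
    return TrainConfig(**kw)


def tiny_overrides(drug, prot):
    return {"drug": TINY[drug], "protein": TINY[prot], "decoder_hidden": (16, 8)}


class TestTrain:
    def test_history_has_one_record_per_epoch(self, small_splits):
        m = train_eval.train("morgan", "aac", small_splits, tiny_cfg(epochs=3),
                             tiny_overrides("morgan", "aac"))
        assert len(m.history_) == 3
        assert [r.epoch for r in m.history_] == [0, 1, 2]
        # validation metrics monitored every epoch with the full metric set
        for r in m.history_:
            assert {"mse", "ci", "pearson"} <= set(r.valid_metrics)

    def test_same_seed_identical_final_loss(self, small_splits):
        runs = [train_eval.train("morgan", "aac", small_splits,
                                 tiny_cfg(epochs=2, seed=5),
                                 tiny_overrides("morgan", "aac"))
                for _ in range(2)]
        assert runs[0].history_[-1].train_loss == runs[1].history_[-1].train_loss

    def test_regression_routes_to_mse_and_classification_to_bce(self, small_xy):
        X, y = small_xy
        m = tiny_model("morgan", "aac").fit(X, y)
        # instrumented check: regression loss equals MSE of the first batch
        # at the recorded parameters is hard to freeze; assert the routing
        # through the loss implementation instead
        from dtikit._autograd import Tensor
        scores = Tensor(np.array([0.0, 1.0]))
        reg_loss = m._loss(scores, np.array([0.0, 1.0]))
        assert reg_loss.data == pytest.approx(0.0)
        yb = (y > np.median(y)).astype(float)
        mb = tiny_model("morgan", "aac").fit(X, yb)
        cls_loss = mb._loss(Tensor(np.array([0.0])), np.array([1.0]))
        # BCE of p=0.5 against label 1 is log 2, not 0.25 (which MSE would give)
        assert cls_loss.data == pytest.approx(np.log(2.0), abs=1e-9)

    def test_nan_loss_aborts_with_location(self, small_splits):
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError, match="epoch"):
                train_eval.train("morgan", "aac", small_splits,
                                 tiny_cfg(epochs=1, learning_rate=1e160),
                                 tiny_overrides("morgan", "aac"))

    def test_empty_train_fold_rejected(self, small_dataset):
        sp = dtikit.data_process(small_dataset, "random", seed=0)
        sp.train.pairs = []
        with pytest.raises(ValueError):
            train_eval.train("morgan", "aac", sp, tiny_cfg())


class TestEarlyStopping:
    def test_best_validation_parameters_are_retained(self, small_splits):
        m = train_eval.train("morgan", "aac", small_splits,
                             tiny_cfg(epochs=6, seed=2),
                             tiny_overrides("morgan", "aac"))
        best_epoch = max(
            (r for r in m.history_ if "best" in r.valid_metrics),
            key=lambda r: r.epoch)
        best_ci = best_epoch.valid_metrics["ci"]
        X_v, y_v = _xy(small_splits.valid)
        assert m.score(X_v, y_v) == pytest.approx(best_ci, abs=1e-12)

    def test_patience_stops_training_early(self, small_splits):
        m = train_eval.train("morgan", "aac", small_splits,
                             tiny_cfg(epochs=50, early_stop_patience=2, seed=2),
                             tiny_overrides("morgan", "aac"))
        assert len(m.history_) < 50


class TestEvaluate:
    def test_metric_sets_by_task(self, small_splits):
        m = train_eval.train("morgan", "aac", small_splits, tiny_cfg(),
                             tiny_overrides("morgan", "aac"))
        got = train_eval.evaluate(m, small_splits.test)
        assert set(got) == {"mse", "ci", "pearson"}

    def test_repeated_evaluation_identical(self, small_splits):
        m = train_eval.train("morgan", "aac", small_splits, tiny_cfg(),
                             tiny_overrides("morgan", "aac"))
        assert train_eval.evaluate(m, small_splits.test) == \
            train_eval.evaluate(m, small_splits.test)

    def test_task_mismatch_rejected(self, small_splits, small_dataset):
        m = train_eval.train("morgan", "aac", small_splits, tiny_cfg(),
                             tiny_overrides("morgan", "aac"))
        binary = dtikit.make_binary(
            dtikit.SyntheticSpec(n_drugs=8, n_targets=4, observed_fraction=1.0,
                                 noise_sd=0.2, seed=3))
        with pytest.raises(ValueError, match="task"):
            train_eval.evaluate(m, binary)


class TestHistoryOutput:
    def test_history_tsv_roundtrip(self, tmp_path, small_splits):
        m = train_eval.train("morgan", "aac", small_splits, tiny_cfg(epochs=2),
                             tiny_overrides("morgan", "aac"))
        out = tmp_path / "history.tsv"
        train_eval.write_history(m, out)
        import pandas as pd
        df = pd.read_csv(out, sep="\t")
        assert len(df) == 2
        assert "train_loss" in df.columns and "valid_ci" in df.columns


class TestRandomSearch:
    def test_seeded_search_returns_best_of_trials(self, small_splits):
        grid = {"learning_rate": [1e-3, 1e-2], "batch_size": [4, 8]}
        res = train_eval.random_search(
            "morgan", "aac", small_splits, grid, budget=3,
            cfg=tiny_cfg(), seed=0)
        assert len(res.trials) == 3
        assert res.best_score == max(t["score"] for t in res.trials)
        assert set(res.best_params) == {"learning_rate", "batch_size"}

    def test_same_seed_same_trials(self, small_splits):
        grid = {"learning_rate": [1e-3, 1e-2]}
        a = train_eval.random_search("morgan", "aac", small_splits, grid,
                                     budget=2, cfg=tiny_cfg(), seed=4)
        b = train_eval.random_search("morgan", "aac", small_splits, grid,
                                     budget=2, cfg=tiny_cfg(), seed=4)
        assert [t["params"] for t in a.trials] == [t["params"] for t in b.trials]


class TestTrainConfigValidation:
    def test_nonpositive_controls_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(valid_metric="accuracy")
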