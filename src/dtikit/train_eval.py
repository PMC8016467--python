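"""Training and evaluation wrappers over :class:`~dtikit.models.DTIModel`.

``train`` runs the estimator on a :class:`~dtikit.iodata.SplitResult` with a
:class:`TrainConfig`, monitoring the validation metric each epoch; the loss
is switched automatically (MSE for regression, binary cross-entropy for
classification) and the best-validation parameters are retained.
``evaluate`` computes the task's three metrics on any labelled dataset.
``random_search`` is a seeded random sweep over a declared hyperparameter
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iodata import InteractionDataset, SplitResult
from .metrics import CLASSIFICATION_METRICS, REGRESSION_METRICS  # noqa: F401 (re-export)
from .models import DTIModel

__all__ = ["TrainConfig", "train", "evaluate", "random_search", "history_frame"]


@dataclass
class TrainConfig:
    """Training-loop controls (all overridable from a config file)."""

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    early_stop_patience: int = 0
    valid_metric: str | None = None
    f1_threshold: float = 0.5

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.valid_metric is not None and self.valid_metric not in (
            REGRESSION_METRICS + CLASSIFICATION_METRICS
        ):
            raise ValueError(f"unknown validation metric {self.valid_metric!r}")


def _xy(ds: InteractionDataset):
    pairs = [(s, q) for s, q, _ in ds.triples()]
    return pairs, ds.labels


def train(drug_encoder: str, protein_encoder: str, splits: SplitResult,
          cfg: TrainConfig | None = None, overrides: dict | None = None) -> DTIModel:
    """Fit an encoder pair on a split dataset; returns the fitted estimator."""
    cfg = cfg or TrainConfig()
    if len(splits.train) == 0:
        raise ValueError("training fold is empty")
    overrides = overrides or {}
    est = DTIModel(
        drug_encoder=drug_encoder,
        protein_encoder=protein_encoder,
        drug_config=overrides.get("drug"),
        protein_config=overrides.get("protein"),
        decoder_hidden=tuple(overrides.get("decoder_hidden", (1024, 1024, 512))),
        task="auto",
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        seed=cfg.seed,
        early_stop_patience=cfg.early_stop_patience,
        valid_metric=cfg.valid_metric,
        f1_threshold=cfg.f1_threshold,
    )
    X_train, y_train = _xy(splits.train)
    X_valid, y_valid = (None, None) if len(splits.valid) == 0 else _xy(splits.valid)
    est.fit(X_train, y_train, X_valid=X_valid, y_valid=y_valid)
    return est


def evaluate(model: DTIModel, ds: InteractionDataset) -> dict:
    """Metric map of a fitted model on a labelled dataset (task must match)."""
    if ds.task != model.task_:
        raise ValueError(
            f"dataset task {ds.task!r} does not match model task {model.task_!r}")
    X, y = _xy(ds)
    return model.score_metrics(X, y)


def history_frame(model: DTIModel) -> pd.DataFrame:
    """Per-epoch training history as a DataFrame (one row per EpochRecord)."""
    rows = []
    for rec in model.history_:
        row = {"epoch": rec.epoch, "train_loss": rec.train_loss,
               "timestamp": rec.timestamp}
        row.update({f"valid_{k}": v for k, v in rec.valid_metrics.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_history(model: DTIModel, path) -> None:
    history_frame(model).to_csv(path, sep="\t", index=False)


@dataclass
class SearchResult:
    best_params: dict
    best_score: float
    trials: list = field(default_factory=list)


def random_search(drug_encoder: str, protein_encoder: str, splits: SplitResult,
                  grid: dict, budget: int = 8, cfg: TrainConfig | None = None,
                  seed: int = 0) -> SearchResult:
    """Seeded random search over a hyperparameter grid.

    ``grid`` maps TrainConfig field names (or ``decoder_hidden``) to lists of
    candidate values; ``budget`` trials are sampled uniformly with
    replacement and scored by the validation metric (CI or AUROC).
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    trials = []
    best_score, best_params = -np.inf, None
    for t in range(budget):
        choice = {k: v[rng.integers(len(v))] for k, v in grid.items()}
        trial_cfg = TrainConfig(**{
            **{f: getattr(cfg, f) for f in (
                "epochs", "batch_size", "learning_rate", "seed",
                "early_stop_patience", "valid_metric", "f1_threshold")},
            **{k: v for k, v in choice.items() if k != "decoder_hidden"},
        })
        overrides = {}
        if "decoder_hidden" in choice:
            overrides["decoder_hidden"] = choice["decoder_hidden"]
        est = train(drug_encoder, protein_encoder, splits, trial_cfg, overrides)
        fold = splits.valid if len(splits.valid) else splits.test
        score = est.score(*_xy(fold))
        trials.append({"params": choice, "score": score})
        if score > best_score:
            best_score, best_params = score, choice
    return SearchResult(best_params=best_params, best_score=best_score, trials=trials)
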