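"""Repurposing and virtual screening: ensemble inference and ranked lists.

``repurpose`` scores a compound library against one disease target;
``virtual_screen`` scores arbitrary compound-target pairs.  Given a training
set, each trains the five default encoder-pair configurations (one per
encoder family), scores every pair with each model and aggregates by the
unweighted mean; without a training set a previously saved model directory
must be supplied.  The output is a descriptive ranked list: highest
predicted binding first, ties broken by compound id for stable output.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DEFAULTS
from .iodata import CompoundRecord, InteractionDataset, ProteinRecord, data_process
from .models import DTIModel, load_model
from .train_eval import TrainConfig, train

__all__ = [
    "RankedList",
    "aggregate_scores",
    "train_ensemble",
    "repurpose",
    "virtual_screen",
    "write_ranked_list",
]

ENSEMBLE_PAIRS = tuple(tuple(p) for p in DEFAULTS["ensemble"])


@dataclass
class RankedList:
    """Ordered (rank, compound, target, aggregate score, per-model scores)."""

    rows: list  # list of dicts: rank, compound_id, target_id, score, model_scores
    models: list
    task: str
    timestamp: float = field(default_factory=time.time)

    def __post_init__(self):
        for i, row in enumerate(self.rows):
            if row["rank"] != i + 1:
                raise ValueError("ranks must be contiguous from 1")
            if i and self.rows[i - 1]["score"] < row["score"]:
                raise ValueError("scores must be non-increasing")
            if len(row["model_scores"]) != len(self.models):
                raise ValueError("per-model score count must equal ensemble size")

    def __len__(self) -> int:
        return len(self.rows)

    def top(self, n: int) -> list:
        return self.rows[:n]


def aggregate_scores(per_model) -> np.ndarray:
    """Arithmetic mean across models for every pair.

    ``per_model``: (n_pairs, n_models) matrix; ragged input is rejected.
    """
    arr = np.asarray(per_model, dtype=float)
    if arr.ndim != 2:
        raise ValueError("per-model scores must form a (n_pairs, n_models) matrix")
    if arr.shape[1] < 1:
        raise ValueError("need at least one model")
    return arr.mean(axis=1)


def train_ensemble(train_set: InteractionDataset, cfg: TrainConfig | None = None,
                   overrides: dict | None = None, split_seed: int = 0) -> list:
    """Train the five default encoder-pair configurations on one dataset."""
    cfg = cfg or TrainConfig()
    splits = data_process(train_set, method="random", fractions=(0.8, 0.1, 0.1),
                          seed=split_seed)
    return [train(d, p, splits, cfg, overrides) for d, p in ENSEMBLE_PAIRS]


def _ensemble_for(train_set, models, cfg, overrides):
    if models is not None:
        out = []
        for m in models:
            if isinstance(m, (str, Path)):
                m = load_model(m)
            if not isinstance(m, DTIModel):
                raise TypeError("models must be DTIModel instances or saved-model paths")
            out.append(m)
        if not out:
            raise ValueError("models list is empty")
        return out
    if train_set is None:
        raise ValueError(
            "no training set and no saved model given: pass train_set=... to train "
            "the default five-model ensemble, or models=[path_or_model, ...] to "
            "reuse previously saved models")
    return train_ensemble(train_set, cfg)


def _ranked(pairs, models, tie_key) -> RankedList:
    per_model = np.column_stack([
        m.predict([(c.smiles, t.sequence) for c, t in pairs]) for m in models
    ])
    agg = aggregate_scores(per_model)
    order = sorted(range(len(pairs)), key=lambda i: (-agg[i], tie_key(pairs[i])))
    rows = []
    for rank, i in enumerate(order, start=1):
        c, t = pairs[i]
        rows.append({
            "rank": rank, "compound_id": c.id, "target_id": t.id,
            "score": float(agg[i]),
            "model_scores": [float(s) for s in per_model[i]],
        })
    task = models[0].task_
    names = [f"{m.drug_encoder}+{m.protein_encoder}" for m in models]
    return RankedList(rows=rows, models=names, task=task)


def repurpose(target: ProteinRecord, library,
              train_set: InteractionDataset | None = None,
              models=None, cfg: TrainConfig | None = None,
              overrides: dict | None = None) -> RankedList:
    """Rank a compound library against one target by predicted binding."""
    library = list(library)
    if not library:
        raise ValueError("compound library must be nonempty")
    ensemble = _ensemble_for(train_set, models, cfg, overrides)
    pairs = [(c, target) for c in library]
    return _ranked(pairs, ensemble, tie_key=lambda p: p[0].id)


def virtual_screen(pairs, train_set: InteractionDataset | None = None,
                   models=None, cfg: TrainConfig | None = None,
                   overrides: dict | None = None) -> RankedList:
    """Rank arbitrary (compound, target) pairs by predicted binding."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("pair list must be nonempty")
    for c, t in pairs:
        if not isinstance(c, CompoundRecord) or not isinstance(t, ProteinRecord):
            raise TypeError("pairs must be (CompoundRecord, ProteinRecord)")
    ensemble = _ensemble_for(train_set, models, cfg, overrides)
    return _ranked(pairs, ensemble, tie_key=lambda p: (p[0].id, p[1].id))


def write_ranked_list(rl: RankedList, path) -> None:
    """Write a ranked list as TSV with a commented descriptive header block."""
    with open(path, "w") as fh:
        fh.write(f"# dtikit ranked list | task: {rl.task}\n")
        fh.write(f"# models ({len(rl.models)}): {', '.join(rl.models)}\n")
        fh.write(f"# generated: {time.strftime('%Y-%m-%d %H:%M:%S', time.gmtime(rl.timestamp))} UTC\n")
        fh.write("rank\tcompound_id\ttarget_id\tscore\t" +
                 "\t".join(f"score_model_{i+1}" for i in range(len(rl.models))) + "\n")
        for row in rl.rows:
            fh.write(f"{row['rank']}\t{row['compound_id']}\t{row['target_id']}\t"
                     f"{row['score']:.6f}\t" +
                     "\t".join(f"{s:.6f}" for s in row["model_scores"]) + "\n")
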