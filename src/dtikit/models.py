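"""Model assembly and the scikit-learn style estimator surface.

A DTI model is an encoder pair plus an MLP decoder: the drug embedding and
the protein embedding are concatenated and decoded to a single score
(unbounded affinity for regression, logistic probability for
classification).  :class:`DTIModel` wraps the whole pipeline —
featurization, architecture, training loop, early stopping — as a
scikit-learn estimator: ``fit(X, y)`` on (SMILES, sequence) pairs,
``predict(X)``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore.  It composes with sklearn model selection; the
module-level :func:`assemble` and the ``train``/``evaluate`` wrappers in
:mod:`dtikit.train_eval` stay thin layers over it.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._autograd import Tensor, concat, no_grad
from ._layers import MLP, Linear, Module
from .bpe import SubstructureVocab, read_vocab, write_vocab
from .config import DEFAULTS, merge_config
from .encoders import (
    EncoderSpec,
    build_encoder,
    featurize_batch,
    make_encoder_spec,
    needs_vocab,
    train_vocab_for,
)
from .iodata import detect_task
from .metrics import evaluate_predictions

__all__ = ["ModelSpec", "DTINetwork", "DTIModel", "assemble", "load_model"]

SAVE_FORMAT_TAG = "dtikit-model-v1"


@dataclass
class ModelSpec:
    """Encoder pair + decoder shape + task kind."""

    drug_encoder: EncoderSpec
    protein_encoder: EncoderSpec
    decoder_hidden: list
    task: str = "regression"

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if not self.decoder_hidden or any(int(h) <= 0 for h in self.decoder_hidden):
            raise ValueError("decoder_hidden must be a nonempty list of positive ints")

    @property
    def decoder_input_dim(self) -> int:
        return self.drug_encoder.output_dim + self.protein_encoder.output_dim


def assemble(drug_name: str, protein_name: str, overrides: dict | None = None,
             task: str = "regression") -> ModelSpec:
    """Resolve two registry names (plus config overrides) into a ModelSpec."""
    overrides = overrides or {}
    drug = make_encoder_spec(drug_name, "drug", overrides.get("drug"))
    prot = make_encoder_spec(protein_name, "protein", overrides.get("protein"))
    decoder_hidden = list(overrides.get("decoder_hidden", DEFAULTS["decoder"]["hidden"]))
    return ModelSpec(drug_encoder=drug, protein_encoder=prot,
                     decoder_hidden=decoder_hidden, task=task)


class DTINetwork(Module):
    """The assembled encoder-decoder network."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 drug_vocab: SubstructureVocab | None = None,
                 protein_vocab: SubstructureVocab | None = None):
        super().__init__()
        self.spec = spec
        self.drug_enc = self.add_module(
            "drug", build_encoder(spec.drug_encoder, rng, drug_vocab))
        self.prot_enc = self.add_module(
            "protein", build_encoder(spec.protein_encoder, rng, protein_vocab))
        dims = list(spec.decoder_hidden)
        self.decoder = self.add_module(
            "decoder", MLP(rng, spec.decoder_input_dim, dims))
        self.head = self.add_module("head", Linear(rng, dims[-1], 1))

    def __call__(self, drug_batch, prot_batch) -> Tensor:
        d = self.drug_enc(drug_batch)
        p = self.prot_enc(prot_batch)
        h = self.decoder(concat([d, p], axis=1))
        return self.head(h).reshape(-1)


class _Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class EpochRecord:
    """One training epoch: loss plus the validation metric map."""

    epoch: int
    train_loss: float
    valid_metrics: dict = field(default_factory=dict)
    timestamp: float = 0.0


def _as_pairs(X) -> list:
    """Normalize input to a list of (smiles, sequence) string pairs."""
    if isinstance(X, pd.DataFrame):
        cols = [c for c in ("smiles", "target_sequence") if c in X.columns]
        if len(cols) == 2:
            return list(zip(X["smiles"], X["target_sequence"]))
        if X.shape[1] >= 2:
            return list(zip(X.iloc[:, 0], X.iloc[:, 1]))
        raise ValueError("DataFrame needs smiles and target_sequence columns")
    pairs = [(str(a), str(b)) for a, b in X]
    return pairs


class DTIModel(BaseEstimator):
    """Drug-target interaction model: encoder pair + MLP decoder.

    Parameters
    ----------
    drug_encoder, protein_encoder
        Registry names (see :mod:`dtikit.encoders`).
    drug_config, protein_config
        Hyperparameter overrides for the two encoders.
    decoder_hidden
        Hidden-layer widths of the MLP decoder.
    task
        ``"auto"`` detects classification when all labels are 0/1.
    epochs, batch_size, learning_rate, seed
        Training-loop controls; the seed fixes initialization and batching,
        so identical configurations train to identical parameters.
    early_stop_patience
        Stop after this many epochs without validation improvement
        (0 disables); the best-validation parameters are retained either way
        when a validation set is given.
    valid_metric
        Metric watched for early stopping; default CI (regression) or
        AUROC (classification).
    """

    def __init__(self, drug_encoder: str = "morgan", protein_encoder: str = "aac",
                 drug_config: dict | None = None, protein_config: dict | None = None,
                 decoder_hidden=(1024, 1024, 512), task: str = "auto",
                 epochs: int = 10, batch_size: int = 32, learning_rate: float = 1e-3,
                 seed: int = 0, early_stop_patience: int = 0,
                 valid_metric: str | None = None, f1_threshold: float = 0.5):
        self.drug_encoder = drug_encoder
        self.protein_encoder = protein_encoder
        self.drug_config = drug_config
        self.protein_config = protein_config
        self.decoder_hidden = decoder_hidden
        self.task = task
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.early_stop_patience = early_stop_patience
        self.valid_metric = valid_metric
        self.f1_threshold = f1_threshold

    # -- internals ---------------------------------------------------------
    def _featurize(self, pairs, cache):
        drug_batch = featurize_batch(
            self.drug_encoder, [p[0] for p in pairs],
            self.spec_.drug_encoder.hyperparams, self.drug_vocab_, cache)
        prot_batch = featurize_batch(
            self.protein_encoder, [p[1] for p in pairs],
            self.spec_.protein_encoder.hyperparams, self.protein_vocab_, cache)
        return drug_batch, prot_batch

    def _loss(self, scores: Tensor, y: np.ndarray) -> Tensor:
        if self.task_ == "regression":
            diff = scores - Tensor(y)
            return (diff * diff).mean()
        # binary cross-entropy through a numerically safe softplus form
        p = scores.sigmoid()
        eps = 1e-12
        yt = Tensor(y)
        return -(yt * (p + eps).log() + (1.0 - yt) * (1.0 - p + eps).log()).mean()

    def _predict_batch(self, pairs) -> np.ndarray:
        with no_grad():
            drug_batch, prot_batch = self._featurize(pairs, self._cache)
            scores = self.network_(drug_batch, prot_batch).data
        if self.task_ == "classification":
            scores = 1.0 / (1.0 + np.exp(-scores))
        return scores

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y, X_valid=None, y_valid=None):
        """Train on (SMILES, sequence) pairs with real or binary labels."""
        pairs = _as_pairs(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(pairs) != len(y):
            raise ValueError("X and y length mismatch")
        if len(pairs) == 0:
            raise ValueError("cannot fit on an empty dataset")
        self.task_ = detect_task(y) if self.task == "auto" else self.task
        overrides = {}
        if self.drug_config:
            overrides["drug"] = self.drug_config
        if self.protein_config:
            overrides["protein"] = self.protein_config
        overrides["decoder_hidden"] = list(self.decoder_hidden)
        self.spec_ = assemble(self.drug_encoder, self.protein_encoder,
                              overrides, task=self.task_)

        self.drug_vocab_ = None
        self.protein_vocab_ = None
        if needs_vocab(self.drug_encoder):
            self.drug_vocab_ = train_vocab_for(
                self.drug_encoder, [p[0] for p in pairs],
                self.spec_.drug_encoder.hyperparams)
        if needs_vocab(self.protein_encoder):
            self.protein_vocab_ = train_vocab_for(
                self.protein_encoder, [p[1] for p in pairs],
                self.spec_.protein_encoder.hyperparams)

        rng = np.random.default_rng(self.seed)
        self.network_ = DTINetwork(self.spec_, rng,
                                   self.drug_vocab_, self.protein_vocab_)
        self._cache: dict = {}
        params = self.network_.parameters()
        opt = _Adam(params, lr=self.learning_rate)

        watch = self.valid_metric or ("ci" if self.task_ == "regression" else "auroc")
        has_valid = X_valid is not None and y_valid is not None
        valid_pairs = _as_pairs(X_valid) if has_valid else None
        y_valid = np.asarray(y_valid, dtype=float).ravel() if has_valid else None

        self.history_ = []
        best_metric, best_state, patience_left = -np.inf, None, self.early_stop_patience
        n = len(pairs)
        for epoch in range(int(self.epochs)):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, int(self.batch_size)):
                idx = order[start:start + int(self.batch_size)]
                batch_pairs = [pairs[i] for i in idx]
                drug_batch, prot_batch = self._featurize(batch_pairs, self._cache)
                scores = self.network_(drug_batch, prot_batch)
                loss = self._loss(scores, y[idx])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch starting {start}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            rec = EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)),
                              timestamp=time.time())
            if has_valid:
                v_scores = self._predict_batch(valid_pairs)
                rec.valid_metrics = evaluate_predictions(
                    y_valid, v_scores, self.task_, f1_threshold=self.f1_threshold)
                current = rec.valid_metrics[watch]
                if watch == "mse":
                    current = -current
                if current > best_metric:
                    best_metric = current
                    best_state = self.network_.state_dict()
                    rec.valid_metrics["best"] = True
                    patience_left = self.early_stop_patience
                else:
                    patience_left -= 1
            self.history_.append(rec)
            if has_valid and self.early_stop_patience and patience_left <= 0:
                break
        if best_state is not None:
            self.network_.load_state_dict(best_state)
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted affinity (regression) or binding probability (classification)."""
        if not hasattr(self, "network_"):
            raise RuntimeError("model is not fitted; call fit() or load_model() first")
        pairs = _as_pairs(X)
        out = []
        for start in range(0, len(pairs), 256):
            out.append(self._predict_batch(pairs[start:start + 256]))
        return np.concatenate(out) if out else np.empty(0)

    def predict_proba(self, X) -> np.ndarray:
        if self.task_ != "classification":
            raise RuntimeError("predict_proba only applies to classification models")
        p = self.predict(X)
        return np.column_stack([1 - p, p])

    def score_metrics(self, X, y) -> dict:
        """Task-appropriate metric map on a labelled set."""
        return evaluate_predictions(np.asarray(y, float).ravel(), self.predict(X),
                                    self.task_, f1_threshold=self.f1_threshold)

    def score(self, X, y) -> float:
        """CI for regression, AUROC for classification (sklearn convention)."""
        m = self.score_metrics(X, y)
        return m["ci"] if self.task_ == "regression" else m["auroc"]

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        """Save spec + parameters + featurizer config to a directory."""
        if not hasattr(self, "network_"):
            raise RuntimeError("cannot save an unfitted model")
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": SAVE_FORMAT_TAG,
            "params": self.get_params(deep=False),
            "task": self.task_,
            "spec": {
                "drug_encoder": asdict(self.spec_.drug_encoder),
                "protein_encoder": asdict(self.spec_.protein_encoder),
                "decoder_hidden": self.spec_.decoder_hidden,
                "task": self.spec_.task,
            },
            "history": [asdict(r) for r in self.history_],
        }
        (d / "model.json").write_text(json.dumps(meta, indent=1, default=list))
        np.savez(d / "parameters.npz", **self.network_.state_dict())
        if self.drug_vocab_ is not None:
            write_vocab(self.drug_vocab_, d / "drug_vocab.tsv")
        if self.protein_vocab_ is not None:
            write_vocab(self.protein_vocab_, d / "protein_vocab.tsv")


def load_model(directory) -> DTIModel:
    """Reload a saved model; predictions are bit-identical to the original."""
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    if meta.get("format") != SAVE_FORMAT_TAG:
        raise ValueError(f"{directory} is not a {SAVE_FORMAT_TAG} directory")
    est = DTIModel(**meta["params"])
    est.task_ = meta["task"]
    spec = meta["spec"]
    est.spec_ = ModelSpec(
        drug_encoder=EncoderSpec(**spec["drug_encoder"]),
        protein_encoder=EncoderSpec(**spec["protein_encoder"]),
        decoder_hidden=list(spec["decoder_hidden"]),
        task=spec["task"],
    )
    est.drug_vocab_ = read_vocab(d / "drug_vocab.tsv") if (d / "drug_vocab.tsv").exists() else None
    est.protein_vocab_ = read_vocab(d / "protein_vocab.tsv") if (d / "protein_vocab.tsv").exists() else None
    rng = np.random.default_rng(est.seed)
    est.network_ = DTINetwork(est.spec_, rng, est.drug_vocab_, est.protein_vocab_)
    with np.load(d / "parameters.npz") as state:
        est.network_.load_state_dict({k: state[k] for k in state.files})
    est.history_ = [EpochRecord(**r) for r in meta["history"]]
    est._cache = {}
    return est
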