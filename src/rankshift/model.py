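"""Two-state transformer classifier over rank encodings.

``StateTransformerClassifier`` is a scikit-learn style estimator: ``fit``
fine-tunes a tiny transformer encoder plus a linear head for the binary
control-vs-disease task, ``predict``/``predict_proba`` score cells, and
``embed`` returns the per-cell embedding (mean of final-encoder-layer hidden
states over non-pad positions) that the perturbation analysis operates on.
An optional masked-gene pretraining pass (``pretrain``) mirrors the
self-supervised objective of transformer foundation models for
transcriptomes: 15% of positions are masked and the original gene token is
predicted from context.

The model tracks a training ``phase_``: "random" after construction,
"pretrained" after masked pretraining, "finetuned" after classification
training. Fine-tuning from a random start is permitted and recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

from . import nn
from .encoding import MASK_TOKEN, PAD_TOKEN, RankEncoding
from .simulate import CONTROL, DISEASE

LABEL_MAP = {CONTROL: 0, DISEASE: 1}
INV_LABEL_MAP = {v: k for k, v in LABEL_MAP.items()}


def _as_token_lists(X) -> list[tuple[int, ...]]:
    out = []
    for enc in X:
        out.append(tuple(enc.tokens) if isinstance(enc, RankEncoding) else tuple(enc))
    return out


@dataclass
class ClassificationReport:
    """Confusion counts (disease = positive class), accuracy, macro-F1 and
    per-cell class probabilities."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    macro_f1: float
    probabilities: pd.DataFrame  # cell_id, p_control, p_disease, label, predicted
    n_excluded: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(
        cls,
        y_true: np.ndarray,
        y_pred: np.ndarray,
        probabilities: pd.DataFrame | None = None,
        n_excluded: int = 0,
    ) -> "ClassificationReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        labels = [CONTROL, DISEASE]
        cm = confusion_matrix(y_true, y_pred, labels=labels)
        tn, fp, fn, tp = cm.ravel()
        if probabilities is None:
            probabilities = pd.DataFrame(
                columns=["cell_id", "p_control", "p_disease", "label", "predicted"]
            )
        return cls(
            tp=int(tp),
            fp=int(fp),
            fn=int(fn),
            tn=int(tn),
            accuracy=float(accuracy_score(y_true, y_pred)),
            macro_f1=float(
                f1_score(y_true, y_pred, labels=labels, average="macro",
                         zero_division=0)
            ),
            probabilities=probabilities,
            n_excluded=n_excluded,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "n_cells": self.n_cells,
            "n_excluded": self.n_excluded,
            "positive_class": DISEASE,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


class StateTransformerClassifier(BaseEstimator, ClassifierMixin):
    """Tiny transformer encoder + linear head for two-state cell classification.

    Parameters
    ----------
    vocab_size : int or None
        Token-table size (max gene token + 1). Inferred from the training
        encodings when None.
    n_layers, n_heads, hidden_dim, context_length, dropout
        Encoder architecture; defaults (2, 4, 64, 128, 0.1) train in minutes
        on one CPU core.
    learning_rate, batch_size, epochs, pretrain_epochs
        Adam optimisation settings shared by pretraining and fine-tuning.
    class_weight : "balanced" or None
        "balanced" weights the cross-entropy by inverse class frequency.
    validation_fraction : float
        Held-out fraction (stratified) logged during fine-tuning.
    seed : int
        Drives initialisation, shuffling, masking and dropout; fixed seed
        gives bit-identical training trajectories.
    """

    def __init__(
        self,
        vocab_size: int | None = None,
        n_layers: int = 2,
        n_heads: int = 4,
        hidden_dim: int = 64,
        context_length: int = 128,
        dropout: float = 0.1,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        epochs: int = 4,
        pretrain_epochs: int = 3,
        class_weight: str | None = "balanced",
        validation_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.vocab_size = vocab_size
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.hidden_dim = hidden_dim
        self.context_length = context_length
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.pretrain_epochs = pretrain_epochs
        self.class_weight = class_weight
        self.validation_fraction = validation_fraction
        self.seed = seed

    # ------------------------------------------------------------------ setup

    def _ensure_net(self, token_lists) -> None:
        if getattr(self, "net_", None) is not None:
            return
        max_token = max(max(t) for t in token_lists if t)
        vocab_size = self.vocab_size
        if vocab_size is None:
            vocab_size = max_token + 1
        elif vocab_size < max_token + 1:
            raise ValueError(
                f"vocab_size {vocab_size} < max token + 1 ({max_token + 1})"
            )
        self.vocab_size_ = int(vocab_size)
        self.net_ = nn.TinyTransformerEncoder(
            vocab_size=self.vocab_size_,
            d_model=self.hidden_dim,
            n_layers=self.n_layers,
            n_heads=self.n_heads,
            context_length=self.context_length,
            dropout=self.dropout,
            seed=self.seed,
        )
        rng = np.random.default_rng(self.seed + 1)
        d = self.hidden_dim
        self.net_.params["mlm.W"] = (
            0.02 * rng.standard_normal((d, self.vocab_size_))
        ).astype(np.float32)
        self.net_.params["mlm.b"] = np.zeros(self.vocab_size_, np.float32)
        self.net_.params["cls.W"] = (0.02 * rng.standard_normal((d, 2))).astype(
            np.float32
        )
        self.net_.params["cls.b"] = np.zeros(2, np.float32)
        self.phase_ = "random"

    def _check_fitted(self, phases=("pretrained", "finetuned")) -> None:
        if getattr(self, "net_", None) is None or getattr(self, "phase_", "random") not in phases:
            raise NotFittedError(
                f"model phase is {getattr(self, 'phase_', 'random')!r}; "
                f"expected one of {phases}"
            )

    # ------------------------------------------------------------ pretraining

    def pretrain(self, X) -> "StateTransformerClassifier":
        """Masked-gene pretraining: mask 15% of positions, predict the token."""
        token_lists = _as_token_lists(X)
        if len(token_lists) < 100:
            raise ValueError(
                f"pretraining needs >= 100 encodings, got {len(token_lists)}"
            )
        self._ensure_net(token_lists)
        if self.phase_ != "random":
            raise ValueError(f"cannot pretrain a model in phase {self.phase_!r}")
        rng = np.random.default_rng(self.seed + 2)
        opt = nn.Adam(self.net_.params, lr=self.learning_rate)
        tokens_all = nn.pad_batch(token_lists, self.context_length)
        n = tokens_all.shape[0]
        self.pretrain_loss_history_ = []
        for _ in range(self.pretrain_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                batch = tokens_all[order[start : start + self.batch_size]]
                loss = self._mlm_step(batch, rng, opt)
                losses.append(loss)
            self.pretrain_loss_history_.append(float(np.mean(losses)))
        self.phase_ = "pretrained"
        return self

    def _mask_batch(self, batch: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
        nonpad = batch != PAD_TOKEN
        u = rng.random(batch.shape)
        mask = (u < 0.15) & nonpad
        # guarantee at least one masked position per non-empty sequence
        for i in np.flatnonzero(nonpad.any(1) & ~mask.any(1)):
            pos = rng.integers(0, nonpad[i].sum())
            mask[i, pos] = True
        masked = batch.copy()
        masked[mask] = MASK_TOKEN
        return masked, mask

    def _mlm_step(self, batch, rng, opt) -> float:
        masked, mask = self._mask_batch(batch, rng)
        H, cache = self.net_.forward(masked, train=True, rng=rng)
        p = self.net_.params
        hsel = H[mask]  # (M, d)
        logits = hsel @ p["mlm.W"] + p["mlm.b"]
        targets = batch[mask]
        probs = nn.softmax(logits)
        M = len(targets)
        loss = float(-np.log(probs[np.arange(M), targets] + 1e-12).mean())
        dlogits = probs
        dlogits[np.arange(M), targets] -= 1.0
        dlogits /= M
        grads = {
            "mlm.W": hsel.T @ dlogits,
            "mlm.b": dlogits.sum(0),
        }
        dH = np.zeros_like(H)
        dH[mask] = dlogits @ p["mlm.W"].T
        grads.update(self.net_.backward(cache, dH))
        opt.step(grads)
        return loss

    def masked_prediction_accuracy(self, X, seed: int = 0) -> float:
        """Fraction of masked positions whose original token is the argmax."""
        self._check_fitted(("pretrained", "finetuned"))
        token_lists = _as_token_lists(X)
        batch = nn.pad_batch(token_lists, self.context_length)
        rng = np.random.default_rng(seed)
        masked, mask = self._mask_batch(batch, rng)
        H, _ = self.net_.forward(masked, train=False)
        p = self.net_.params
        logits = H[mask] @ p["mlm.W"] + p["mlm.b"]
        return float((logits.argmax(1) == batch[mask]).mean())

    # ------------------------------------------------------------- finetuning

    def fit(self, X, y) -> "StateTransformerClassifier":
        """Fine-tune for control-vs-disease classification with cross-entropy."""
        token_lists = _as_token_lists(X)
        y = np.asarray(y, dtype=object)
        classes = sorted(set(y))
        if len(classes) < 2:
            raise ValueError(
                f"training data contains a single class {classes}; both "
                f"{CONTROL!r} and {DISEASE!r} are required"
            )
        unknown = set(classes) - set(LABEL_MAP)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")
        self._ensure_net(token_lists)
        started_from = self.phase_
        yi = np.array([LABEL_MAP[v] for v in y])

        rng = np.random.default_rng(self.seed + 3)
        n = len(token_lists)
        n_val = int(round(self.validation_fraction * n))
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(set(yi[train_idx])) < 2:  # degenerate split on tiny data
            train_idx = order
            val_idx = np.array([], dtype=int)

        if self.class_weight == "balanced":
            counts = np.bincount(yi[train_idx], minlength=2)
            w = len(train_idx) / (2.0 * np.maximum(counts, 1))
        else:
            w = np.ones(2)
        weights = w.astype(np.float32)

        tokens_all = nn.pad_batch(token_lists, self.context_length)
        opt = nn.Adam(self.net_.params, lr=self.learning_rate)
        self.loss_history_ = []
        for _ in range(self.epochs):
            ep_order = train_idx[rng.permutation(len(train_idx))]
            losses = []
            for start in range(0, len(ep_order), self.batch_size):
                idx = ep_order[start : start + self.batch_size]
                loss = self._cls_step(tokens_all[idx], yi[idx], weights, rng, opt)
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
        self.phase_ = "finetuned"
        self.classes_ = np.array([CONTROL, DISEASE], dtype=object)
        self.started_from_phase_ = started_from
        self.train_indices_ = train_idx
        self.validation_indices_ = val_idx
        if len(val_idx):
            val_pred = self.predict([token_lists[i] for i in val_idx])
            self.validation_accuracy_ = float(
                np.mean(val_pred == np.array([INV_LABEL_MAP[v] for v in yi[val_idx]]))
            )
        else:
            self.validation_accuracy_ = float("nan")
        return self

    def _cls_step(self, batch, yb, weights, rng, opt) -> float:
        H, cache = self.net_.forward(batch, train=True, rng=rng)
        p = self.net_.params
        pooled = nn.mean_pool(H, batch)
        logits = pooled @ p["cls.W"] + p["cls.b"]
        probs = nn.softmax(logits)
        B = len(yb)
        wvec = weights[yb]
        loss = float((-np.log(probs[np.arange(B), yb] + 1e-12) * wvec).sum() / wvec.sum())
        dlogits = probs.copy()
        dlogits[np.arange(B), yb] -= 1.0
        dlogits *= (wvec / wvec.sum())[:, None]
        grads = {
            "cls.W": pooled.T @ dlogits,
            "cls.b": dlogits.sum(0),
        }
        dpooled = dlogits @ p["cls.W"].T
        dH = nn.mean_pool_backward(dpooled, batch, batch.shape[1])
        grads.update(self.net_.backward(cache, dH))
        opt.step(grads)
        return loss

    # -------------------------------------------------------------- inference

    def _forward_batched(self, token_lists, batch_size: int = 128) -> np.ndarray:
        """Pooled embeddings for a list of token sequences."""
        out = np.empty((len(token_lists), self.hidden_dim), dtype=np.float32)
        for start in range(0, len(token_lists), batch_size):
            chunk = token_lists[start : start + batch_size]
            batch = nn.pad_batch(chunk, self.context_length)
            H, _ = self.net_.forward(batch, train=False)
            out[start : start + len(chunk)] = nn.mean_pool(H, batch)
        return out

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted(("finetuned",))
        pooled = self._forward_batched(_as_token_lists(X))
        p = self.net_.params
        return nn.softmax(pooled @ p["cls.W"] + p["cls.b"]).astype(np.float64)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.array([INV_LABEL_MAP[i] for i in probs.argmax(1)], dtype=object)

    def embed(self, X) -> np.ndarray:
        """Per-cell embedding: mean of final-encoder-layer states over non-pad
        positions. Requires a pretrained or finetuned model."""
        self._check_fitted(("pretrained", "finetuned"))
        token_lists = _as_token_lists(X)
        for t in token_lists:
            if len(t) > self.context_length:
                raise ValueError(
                    f"encoding of length {len(t)} exceeds context length "
                    f"{self.context_length}; truncate before embedding"
                )
        return self._forward_batched(token_lists)

    def evaluate(self, X, y, cell_ids=None, n_excluded: int = 0) -> ClassificationReport:
        """Classify and summarise into a report (disease = positive class)."""
        self._check_fitted(("finetuned",))
        probs = self.predict_proba(X)
        y_pred = np.array([INV_LABEL_MAP[i] for i in probs.argmax(1)], dtype=object)
        if cell_ids is None:
            cell_ids = [getattr(e, "cell_id", str(i)) for i, e in enumerate(X)]
        table = pd.DataFrame(
            {
                "cell_id": list(cell_ids),
                "p_control": probs[:, 0],
                "p_disease": probs[:, 1],
                "label": list(y),
                "predicted": list(y_pred),
            }
        )
        report = ClassificationReport.from_predictions(
            np.asarray(y, dtype=object), y_pred, table, n_excluded=n_excluded
        )
        report.metadata["phase"] = self.phase_
        return report

    # ------------------------------------------------------------ persistence

    def save(self, path: str | Path) -> None:
        self._check_fitted(("pretrained", "finetuned"))
        config = {k: v for k, v in self.get_params().items()}
        meta = {
            "config": config,
            "phase": self.phase_,
            "vocab_size": self.vocab_size_,
            "loss_history": getattr(self, "loss_history_", []),
            "pretrain_loss_history": getattr(self, "pretrain_loss_history_", []),
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
            **self.net_.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "StateTransformerClassifier":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
            params = {k: archive[k] for k in archive.files if k != "__meta__"}
        model = cls(**meta["config"])
        model.vocab_size_ = meta["vocab_size"]
        model.net_ = nn.TinyTransformerEncoder(
            vocab_size=meta["vocab_size"],
            d_model=model.hidden_dim,
            n_layers=model.n_layers,
            n_heads=model.n_heads,
            context_length=model.context_length,
            dropout=model.dropout,
            seed=model.seed,
        )
        model.net_.params = params
        model.phase_ = meta["phase"]
        model.loss_history_ = meta["loss_history"]
        model.pretrain_loss_history_ = meta["pretrain_loss_history"]
        model.classes_ = np.array([CONTROL, DISEASE], dtype=object)
        return model
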