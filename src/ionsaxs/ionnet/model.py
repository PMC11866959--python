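"""The Mg2+ site classifier: a small graph neural network.

Architecture (defaults, all configurable): two graph attention layers
followed by two graph convolution layers (hidden width 64), a mean-pool
read-out and a sigmoid head.  Trained with binary cross-entropy and Adam on
minibatches of packed graphs.  The whole model is plain numpy; a forward
pass is deterministic given fixed weights, and the output probability is
invariant to rigid motions of the source structure because the input graphs
encode only distances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..probes import NODE_FEATURE_DIM, NeighborhoodGraph, feature_schema
from .graphs import GraphBatch, pack, prepare_graph
from .layers import (gat_backward, gat_forward, gat_init, gcn_backward,
                     gcn_forward, gcn_init, head_backward, head_forward,
                     head_init)

__all__ = ["Hyperparameters", "ClassifierModel", "SchemaMismatchError"]

_CHECKPOINT_VERSION = 1


class SchemaMismatchError(ValueError):
    """Input features do not match the schema the model was trained with."""


def _schema_hash() -> str:
    return hashlib.sha256(feature_schema().encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Hyperparameters:
    hidden: int = 64
    n_attention: int = 2
    n_convolution: int = 2
    learning_rate: float = 5e-3
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0


class ClassifierModel:
    """Graph classifier scoring a probe neighborhood as Mg2+ vs water."""

    def __init__(self, hyper: Hyperparameters | None = None):
        self.hyper = hyper or Hyperparameters()
        self.schema_hash = _schema_hash()
        rng = np.random.default_rng(self.hyper.seed)
        self.params: dict[str, np.ndarray] = {}
        self._layers: list[tuple[str, str]] = []
        fan_in = NODE_FEATURE_DIM
        for i in range(self.hyper.n_attention):
            name = f"gat{i}"
            self.params.update(gat_init(rng, fan_in, self.hyper.hidden, name))
            self._layers.append(("gat", name))
            fan_in = self.hyper.hidden
        for i in range(self.hyper.n_convolution):
            name = f"gcn{i}"
            self.params.update(gcn_init(rng, fan_in, self.hyper.hidden, name))
            self._layers.append(("gcn", name))
            fan_in = self.hyper.hidden
        self.params.update(head_init(rng, fan_in))
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.epoch_losses: list[float] = []

    # -- forward / backward -------------------------------------------------

    def forward(self, batch: GraphBatch):
        """Logits for every graph in the batch (with caches for backprop)."""
        X = batch.X
        caches = []
        for kind, name in self._layers:
            fwd = gat_forward if kind == "gat" else gcn_forward
            X, cache = fwd(self.params, name, X, batch)
            caches.append(cache)
        logits, head_cache = head_forward(self.params, X, batch)
        return logits, (caches, head_cache)

    def loss_and_grads(self, batch: GraphBatch):
        """Mean binary cross-entropy over the batch and all parameter grads."""
        if batch.labels is None:
            raise ValueError("batch must be fully labeled")
        logits, (caches, head_cache) = self.forward(batch)
        y = batch.labels
        # stable BCE with logits
        loss = float(np.mean(np.maximum(logits, 0) - logits * y
                             + np.log1p(np.exp(-np.abs(logits)))))
        dlogits = (_sigmoid(logits) - y) / y.size
        grads: dict[str, np.ndarray] = {}
        dX, g = head_backward(self.params, dlogits, head_cache, batch)
        grads.update(g)
        for (kind, name), cache in zip(reversed(self._layers), reversed(caches)):
            bwd = gat_backward if kind == "gat" else gcn_backward
            dX, g = bwd(self.params, name, dX, cache, batch)
            grads.update(g)
        return loss, grads

    def _adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training -----------------------------------------------------------

    def fit(self, graphs: Sequence[NeighborhoodGraph],
            rng: np.random.Generator | None = None) -> "ClassifierModel":
        """Train in place on labeled graphs; records per-epoch mean loss.

        Class imbalance is handled by subsampling the majority class to 1:1
        each epoch.
        """
        labels = np.array([g.label for g in graphs], dtype=object)
        if any(l is None for l in labels):
            raise ValueError("all training graphs must be labeled")
        y = labels.astype(int)
        if len(set(y.tolist())) < 2:
            raise ValueError("training set must contain both classes")
        prepared = [prepare_graph(g) for g in graphs]
        rng = rng or np.random.default_rng(self.hyper.seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        n_per = min(pos_idx.size, neg_idx.size)

        for _ in range(self.hyper.epochs):
            take_pos = rng.choice(pos_idx, n_per, replace=False)
            take_neg = rng.choice(neg_idx, n_per, replace=False)
            order = np.concatenate([take_pos, take_neg])
            rng.shuffle(order)
            losses = []
            for start in range(0, order.size, self.hyper.batch_size):
                idx = order[start:start + self.hyper.batch_size]
                batch = pack([prepared[i] for i in idx])
                loss, grads = self.loss_and_grads(batch)
                self._adam_step(grads, self.hyper.learning_rate)
                losses.append(loss)
            self.epoch_losses.append(float(np.mean(losses)))
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, graphs: Sequence[NeighborhoodGraph]) -> np.ndarray:
        """Mg2+ probability for each graph, in [0, 1]."""
        if not len(graphs):
            return np.empty(0)
        for g in graphs:
            if g.node_features.shape[1] != NODE_FEATURE_DIM:
                raise SchemaMismatchError("node feature width mismatch")
        logits, _ = self.forward(pack(list(graphs)))
        return _sigmoid(logits)

    def predict(self, graph: NeighborhoodGraph) -> float:
        return float(self.predict_proba([graph])[0])

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing, versioned checkpoint (npz)."""
        meta = {
            "version": _CHECKPOINT_VERSION,
            "schema": feature_schema(),
            "schema_hash": self.schema_hash,
            "hyper": self.hyper.__dict__,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **self.params)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["schema_hash"] != _schema_hash():
                raise SchemaMismatchError(
                    "checkpoint was trained with a different feature schema")
            model = cls(Hyperparameters(**meta["hyper"]))
            for k in model.params:
                model.params[k] = data[k]
        return model


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
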