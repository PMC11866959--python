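"""Cross-validated training of the site classifier."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ..probes import NeighborhoodGraph
from .model import ClassifierModel, Hyperparameters

__all__ = ["TrainingResult", "train"]


@dataclass(frozen=True)
class TrainingResult:
    """Final model plus k-fold generalization estimates."""

    model: ClassifierModel
    fold_aurocs: np.ndarray
    auroc_mean: float
    auroc_sd: float

    def report(self) -> str:
        """Tab-separated per-fold metrics."""
        lines = ["fold\tauroc"]
        lines += [f"{i + 1}\t{a:.4f}" for i, a in enumerate(self.fold_aurocs)]
        lines.append(f"mean\t{self.auroc_mean:.4f}")
        lines.append(f"sd\t{self.auroc_sd:.4f}")
        return "\n".join(lines)


def train(dataset: Sequence[NeighborhoodGraph], folds: int = 4, seed: int = 0,
          hyper: Hyperparameters | None = None) -> TrainingResult:
    """K-fold cross-validation followed by training on the full set.

    Every fold must contain both classes; the returned AUROCs are measured
    on the held-out fold of each split.  Fully reproducible for a fixed
    seed.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    dataset = list(dataset)
    labels = [g.label for g in dataset]
    if any(l is None for l in labels):
        raise ValueError("dataset must be fully labeled")
    y = np.array(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("dataset must contain both classes")

    hyper = hyper or Hyperparameters(seed=seed)
    if hyper.seed != seed:
        hyper = Hyperparameters(**{**hyper.__dict__, "seed": seed})

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aurocs = []
    for k, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        fold_hyper = Hyperparameters(**{**hyper.__dict__, "seed": seed + 1 + k})
        m = ClassifierModel(fold_hyper)
        m.fit([dataset[i] for i in tr])
        p = m.predict_proba([dataset[i] for i in te])
        aurocs.append(roc_auc_score(y[te], p))
    aurocs = np.array(aurocs)

    final = ClassifierModel(hyper)
    final.fit(dataset)
    return TrainingResult(model=final, fold_aurocs=aurocs,
                          auroc_mean=float(aurocs.mean()),
                          auroc_sd=float(aurocs.std(ddof=1)))
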