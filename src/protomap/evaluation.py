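"""Classification and integration scoring conventions.

Label transfer is scored with per-class F1 aggregated two ways: weighted by
class support and unweighted (macro). Integration quality combines a batch
mixing score and a biological conservation score as the fixed weighted
average 0.4 * batch + 0.6 * bio. A native kNN batch-mixing surrogate is
provided for desk-scale use; the full external metric suites plug in as
plain lists of [0, 1] component scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScoreReport", "f1_scores", "overall_integration_score", "batch_mixing_knn"]


@dataclass
class ScoreReport:
    per_class_f1: dict[str, float] = field(default_factory=dict)
    weighted_f1: float = np.nan
    macro_f1: float = np.nan
    accuracy: float = np.nan
    batch_scores: list[float] = field(default_factory=list)
    bio_scores: list[float] = field(default_factory=list)
    integration_score: float | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=float)


def f1_scores(truth: np.ndarray, predicted: np.ndarray) -> ScoreReport:
    """Per-class, weighted and macro F1 plus accuracy.

    Classes are those with nonzero support in the truth; spurious predicted
    classes contribute to their true class's errors but not to the macro
    average.
    """
    truth = np.asarray(truth, dtype=object).astype(str)
    predicted = np.asarray(predicted, dtype=object).astype(str)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    if truth.size == 0:
        raise ValueError("empty label vectors")
    from sklearn.metrics import f1_score

    classes = sorted(np.unique(truth).tolist())
    per_class = f1_score(truth, predicted, labels=classes, average=None, zero_division=0)
    report = ScoreReport(
        per_class_f1={c: float(v) for c, v in zip(classes, per_class)},
        weighted_f1=float(f1_score(truth, predicted, labels=classes,
                                   average="weighted", zero_division=0)),
        macro_f1=float(f1_score(truth, predicted, labels=classes,
                                average="macro", zero_division=0)),
        accuracy=float((truth == predicted).mean()),
    )
    return report


def overall_integration_score(batch_scores: list[float], bio_scores: list[float]) -> float:
    """0.4 * mean(batch mixing) + 0.6 * mean(biological conservation)."""
    batch_scores = np.asarray(batch_scores, dtype=float)
    bio_scores = np.asarray(bio_scores, dtype=float)
    if batch_scores.size == 0 or bio_scores.size == 0:
        raise ValueError("both score lists must be nonempty")
    for arr in (batch_scores, bio_scores):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("component scores must lie in [0, 1]")
    return float(0.4 * batch_scores.mean() + 0.6 * bio_scores.mean())


def batch_mixing_knn(latents: np.ndarray, batches: np.ndarray, k: int = 15) -> float:
    """Label-free batch-mixing score in [0, 1]; 1 = perfectly mixed.

    For each cell, the fraction of same-batch cells among its k nearest
    neighbors is compared with the chance rate (n_b - 1)/(n - 1) for its
    batch; the mean excess, normalized by the worst case, is subtracted
    from 1. Invariant to isometries of the latent space.
    """
    from sklearn.neighbors import NearestNeighbors

    latents = np.asarray(latents, dtype=float)
    batches = np.asarray(batches, dtype=object).astype(str)
    n = latents.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    levels, inverse = np.unique(batches, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("batch mixing undefined for a single batch")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(latents)
    _, nbrs = nn.kneighbors(latents)
    nbrs = nbrs[:, 1:]  # drop self
    same = (inverse[nbrs] == inverse[:, None]).mean(axis=1)
    sizes = np.bincount(inverse)
    chance = (sizes[inverse] - 1) / (n - 1)
    excess = np.clip((same - chance) / np.maximum(1.0 - chance, 1e-12), 0.0, None)
    return float(np.clip(1.0 - excess.mean(), 0.0, 1.0))
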