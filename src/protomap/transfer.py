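"""Nearest-prototype label transfer with distance-based uncertainty.

A cell is assigned the label of its closest labeled prototype in latent
space (Minkowski distance), and the minimum distance itself is the
uncertainty proxy u_i. The uncertainty has no upper bound; an optional
min-max scaling maps it onto [0, 1]. Cells whose uncertainty exceeds a
population quantile (default the 90% quantile of the classified cells)
are flagged as unknown — candidates for cell types absent from the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prototypes import PrototypeSet

__all__ = ["TransferResult", "classify", "scale_uncertainty", "flag_unknown",
           "threshold_sweep"]

UNKNOWN = "unknown"


@dataclass
class TransferResult:
    cell_ids: list[str]
    predicted: np.ndarray
    uncertainty: np.ndarray
    scaled_uncertainty: np.ndarray | None = None
    unknown: np.ndarray | None = None

    def __post_init__(self):
        if self.unknown is None:
            self.unknown = np.zeros(len(self.predicted), dtype=bool)

    def labels_with_unknown(self) -> np.ndarray:
        """Predictions with flagged cells replaced by the 'unknown' token."""
        out = self.predicted.astype(object).copy()
        out[self.unknown] = UNKNOWN
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell_id": self.cell_ids,
            "predicted_label": self.predicted,
            "uncertainty": self.uncertainty,
        })
        df["scaled_uncertainty"] = (self.scaled_uncertainty
                                    if self.scaled_uncertainty is not None else np.nan)
        df["unknown_flag"] = self.unknown
        return df

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def classify(latents: np.ndarray, prototypes: PrototypeSet, order: float = 2.0,
             cell_ids: list[str] | None = None) -> TransferResult:
    """Assign each cell the label of its nearest labeled prototype.

    Uncertainty is the minimizing distance. Ties break to the
    lexicographically smallest label (prototype rows are sorted by label and
    argmin returns the first minimum).
    """
    if not prototypes.labeled:
        raise ValueError("prototype set has no labeled prototypes")
    latents = np.asarray(latents, dtype=float)
    P = prototypes.matrix()  # rows sorted by label
    labels = np.asarray(prototypes.labels, dtype=object)
    diff = np.abs(latents[:, None, :] - P[None, :, :])
    dist = (diff ** order).sum(axis=2) ** (1.0 / order)
    best = dist.argmin(axis=1)
    u = dist[np.arange(len(latents)), best]
    ids = cell_ids if cell_ids is not None else [str(i) for i in range(len(latents))]
    return TransferResult(list(ids), labels[best], u)


def scale_uncertainty(u: np.ndarray) -> np.ndarray:
    """Min-max scale distances onto [0, 1]; constant input maps to zeros."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("uncertainties must be non-negative")
    lo, hi = u.min(), u.max()
    if hi == lo:
        return np.zeros_like(u)
    return (u - lo) / (hi - lo)


def flag_unknown(result: TransferResult, quantile: float = 0.9) -> TransferResult:
    """Mark cells whose uncertainty exceeds the q-quantile as unknown.

    The quantile is computed over the classified population itself
    (linear-interpolation sample quantile); q = 1 flags nothing and the
    flagged set grows monotonically as q decreases.
    """
    if len(result.uncertainty) == 0:
        raise ValueError("empty transfer result")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must lie in [0, 1]")
    if quantile == 0.0:
        # nothing is trusted: every cell is flagged, including ties at the minimum
        unknown = np.ones(len(result.uncertainty), dtype=bool)
    else:
        cutoff = np.quantile(result.uncertainty, quantile, method="linear")
        unknown = result.uncertainty > cutoff
    return TransferResult(result.cell_ids, result.predicted, result.uncertainty,
                          scaled_uncertainty=scale_uncertainty(result.uncertainty),
                          unknown=unknown)


def threshold_sweep(result: TransferResult, truth: np.ndarray,
                    quantiles: np.ndarray, novel_labels: set[str] | None = None) -> pd.DataFrame:
    """Ratio of true predictions across unknown-detection thresholds.

    For each quantile q a prediction counts as true when either the cell is
    flagged unknown and its true label is novel (absent from the prototype
    labels, or listed in ``novel_labels``), or it is not flagged and the
    predicted label matches the truth.
    """
    truth = np.asarray(truth, dtype=object).astype(str)
    if novel_labels is None:
        known = set(np.unique(result.predicted).astype(str))
        novel = ~np.isin(truth, sorted(known))
    else:
        novel = np.isin(truth, sorted(novel_labels))
    rows = []
    for q in np.asarray(quantiles, dtype=float):
        flagged = flag_unknown(result, q)
        correct = np.where(flagged.unknown, novel,
                           (~novel) & (flagged.predicted.astype(str) == truth))
        rows.append({"quantile": q, "accuracy": float(correct.mean()),
                     "n_unknown": int(flagged.unknown.sum())})
    return pd.DataFrame(rows)
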