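"""Cell-identity prototypes in latent space.

A prototype is the mean latent vector of the cells sharing a label:

    p_k = (1/|K(k)|) sum_{i in K(k)} z_i

Labeled prototypes anchor a supervised pull-in loss during fine-tuning and
drive nearest-prototype label transfer. Cells carrying the UNLABELED
sentinel are clustered (Louvain communities on a kNN graph of the latent
space) and summarized by *unlabeled* prototypes, which are reference points
for downstream analysis and novel-type annotation only — they never enter
the prototype loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import UNLABELED

__all__ = [
    "PrototypeSet",
    "compute_labeled_prototypes",
    "compute_unlabeled_prototypes",
    "minkowski_distance",
    "prototype_loss",
]


@dataclass
class PrototypeSet:
    """Labeled and unlabeled prototypes for one annotation level."""

    annotation_level: str
    labeled: dict[str, np.ndarray] = field(default_factory=dict)
    unlabeled: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: str = "reference"

    def __post_init__(self):
        overlap = set(self.labeled) & set(self.unlabeled)
        if overlap:
            raise ValueError(f"labeled/unlabeled key collision: {sorted(overlap)}")
        dims = {v.shape[-1] for v in list(self.labeled.values()) + list(self.unlabeled.values())}
        if len(dims) > 1:
            raise ValueError("prototype vectors have inconsistent dimensions")

    @property
    def labels(self) -> list[str]:
        return sorted(self.labeled)

    def matrix(self) -> np.ndarray:
        """(K, D) matrix of labeled prototypes, rows ordered by sorted label."""
        return np.stack([self.labeled[k] for k in self.labels])

    def assignment_index(self, annotations: np.ndarray) -> np.ndarray:
        """Row index into :meth:`matrix` per cell; -1 for UNLABELED or unseen."""
        lut = {lab: i for i, lab in enumerate(self.labels)}
        out = np.full(len(annotations), -1, dtype=int)
        for i, a in enumerate(annotations):
            a = str(a)
            if a == UNLABELED:
                continue
            if a not in lut:
                raise KeyError(
                    f"label '{a}' has no prototype at level '{self.annotation_level}'")
            out[i] = lut[a]
        return out

    def merged_with(self, other: "PrototypeSet") -> "PrototypeSet":
        """Union of two sets; entries of ``self`` win on key clashes."""
        lab = {**other.labeled, **self.labeled}
        unl = {**other.unlabeled, **self.unlabeled}
        return PrototypeSet(self.annotation_level, lab, unl, provenance=self.provenance)

    # -- serialization ------------------------------------------------- #
    def to_arrays(self):
        keys = self.labels + sorted(self.unlabeled)
        mat = (np.stack([(self.labeled | self.unlabeled)[k] for k in keys])
               if keys else np.zeros((0, 0)))
        flags = [k in self.unlabeled for k in keys]
        return keys, mat, flags

    @classmethod
    def from_arrays(cls, level, keys, mat, unlabeled_flags, provenance="reference"):
        labeled, unlabeled = {}, {}
        for k, row, flag in zip(keys, mat, unlabeled_flags):
            (unlabeled if flag else labeled)[str(k)] = np.asarray(row)
        return cls(level, labeled, unlabeled, provenance=provenance)

    def to_frame(self) -> pd.DataFrame:
        keys, mat, flags = self.to_arrays()
        df = pd.DataFrame(mat, columns=[f"dim{j}" for j in range(mat.shape[1])])
        df.insert(0, "level", self.annotation_level)
        df.insert(1, "label", keys)
        df.insert(2, "unlabeled", flags)
        return df

    def export_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def import_tsv(cls, path: str) -> "PrototypeSet":
        df = pd.read_csv(path, sep="\t")
        dims = [c for c in df.columns if c.startswith("dim")]
        level = str(df["level"].iloc[0]) if len(df) else "annotation"
        return cls.from_arrays(level, df["label"].astype(str).tolist(),
                               df[dims].to_numpy(), df["unlabeled"].tolist())


def compute_labeled_prototypes(latents: np.ndarray, annotations: np.ndarray,
                               level: str = "cell_type",
                               provenance: str = "reference") -> PrototypeSet:
    """Mean latent vector per label; UNLABELED cells are excluded."""
    latents = np.asarray(latents, dtype=float)
    annotations = np.asarray(annotations, dtype=object).astype(str)
    mask = annotations != UNLABELED
    if not mask.any():
        raise ValueError("no labeled cells: cannot compute labeled prototypes")
    labeled = {}
    for lab in np.unique(annotations[mask]):
        labeled[str(lab)] = latents[annotations == lab].mean(axis=0)
    return PrototypeSet(level, labeled, provenance=provenance)


def compute_unlabeled_prototypes(latents: np.ndarray, level: str = "cell_type",
                                 n_neighbors: int = 15, resolution: float = 1.0,
                                 seed: int = 0,
                                 provenance: str = "reference") -> PrototypeSet:
    """Louvain communities of the latent kNN graph, one prototype each.

    Builds a k-nearest-neighbor graph (Euclidean) over the unlabeled cells
    and runs Louvain community detection (igraph multilevel) at the given
    resolution; each community's mean latent vector becomes an unlabeled
    prototype keyed ``unlabeled_<j>``. An empty input yields an empty set.
    """
    latents = np.asarray(latents, dtype=float)
    if latents.shape[0] == 0:
        return PrototypeSet(level, provenance=provenance)
    if latents.shape[0] == 1:
        return PrototypeSet(level, unlabeled={"unlabeled_0": latents[0].copy()},
                            provenance=provenance)
    import igraph as ig
    from sklearn.neighbors import NearestNeighbors

    k = min(n_neighbors, latents.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(latents)
    _, nbrs = nn.kneighbors(latents)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(nbrs) for j in row if i != j}
    graph = ig.Graph(n=latents.shape[0], edges=sorted(edges))
    clustering = graph.community_multilevel(resolution=resolution)
    membership = np.asarray(clustering.membership)
    unlabeled = {f"unlabeled_{j}": latents[membership == j].mean(axis=0)
                 for j in np.unique(membership)}
    return PrototypeSet(level, unlabeled=unlabeled, provenance=provenance)


def minkowski_distance(z: np.ndarray, p: np.ndarray, order: float = 2.0) -> float | np.ndarray:
    """(sum |z - p|^order)^(1/order); order 2 = Euclidean, 1 = Manhattan.

    Broadcasts over leading axes, so a (n, D) batch against a (D,) prototype
    returns n distances.
    """
    z, p = np.asarray(z, dtype=float), np.asarray(p, dtype=float)
    if z.shape[-1] != p.shape[-1]:
        raise ValueError(f"dimension mismatch: {z.shape[-1]} vs {p.shape[-1]}")
    if order <= 0:
        raise ValueError("Minkowski order must be positive")
    return (np.abs(z - p) ** order).sum(axis=-1) ** (1.0 / order)


def prototype_loss(latents: np.ndarray, annotations_per_level: dict[str, np.ndarray],
                   prototype_sets: dict[str, PrototypeSet], order: float = 2.0) -> float:
    """Supervised pull-in loss, averaged over all N cells in the batch.

    (1/N) * sum over annotation levels, labels and cells of the Minkowski
    distance between a labeled cell and its own prototype; UNLABELED cells
    contribute nothing, and unlabeled (cluster) prototypes are ignored.
    """
    latents = np.asarray(latents, dtype=float)
    n = latents.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    total = 0.0
    for level, annotations in annotations_per_level.items():
        ps = prototype_sets[level]
        assign = ps.assignment_index(np.asarray(annotations))
        labeled = assign >= 0
        if not labeled.any():
            continue
        P = ps.matrix()
        diff = np.abs(latents[labeled] - P[assign[labeled]])
        total += float(((diff ** order).sum(axis=1) ** (1.0 / order)).sum())
    return total / n
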