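"""Sample-level analytics on learned condition embeddings.

The condition-embedding table of a trained model is itself a data matrix:
one row per sample (or study, assay, donor, ...), E columns. This module
provides the standard multi-scale analyses over that matrix — PCA,
covariate association via adjusted R-squared, kNN sample-phenotype
classification with cross-validation, per-sample pseudobulk baselines, and
a gene-by-PC Pearson correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cvae import ConditionEmbeddingTable
from .data import ExpressionDataset

__all__ = [
    "SampleEmbeddingMatrix",
    "AssociationResult",
    "embedding_pca",
    "pc_covariate_association",
    "knn_sample_classifier",
    "pseudobulk_baseline",
    "gene_pc_correlation",
]


@dataclass
class SampleEmbeddingMatrix:
    """Condition-name-indexed embedding matrix with optional metadata."""

    names: list[str]
    matrix: np.ndarray
    metadata: pd.DataFrame | None = None

    @classmethod
    def from_table(cls, table: ConditionEmbeddingTable,
                   metadata: pd.DataFrame | None = None) -> "SampleEmbeddingMatrix":
        if metadata is not None:
            metadata = metadata.loc[table.names]
        return cls(list(table.names), table.matrix.copy(), metadata)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=pd.Index(self.names, name="condition"),
                            columns=[f"dim{j}" for j in range(self.matrix.shape[1])])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class AssociationResult:
    covariate: str
    pc_index: int
    adjusted_r2: float
    r2: float
    n_samples: int
    n_predictors: int


def embedding_pca(m: SampleEmbeddingMatrix, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of the sample embeddings.

    Returns ``(scores, explained_variance_fractions)``. Sign convention:
    each component is flipped so its largest-magnitude loading is positive,
    making the decomposition deterministic across platforms.
    """
    X = np.asarray(m.matrix, dtype=float)
    n, e = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two conditions")
    if n_pcs > min(n - 1, e):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_conditions-1, E)={min(n - 1, e)}")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u[:, :n_pcs] * s[:n_pcs]
    frac = (s ** 2) / (s ** 2).sum()
    return scores, frac[:n_pcs]


def _encode_covariate(values: np.ndarray, kind: str) -> np.ndarray:
    values = np.asarray(values)
    if kind == "ordinal":
        return np.asarray(values, dtype=float).reshape(-1, 1)
    levels = pd.unique(pd.Series(values).astype(str))
    if len(levels) < 2:
        raise ValueError("covariate has a single level; association undefined")
    # dummy encoding, first level as baseline -> p = levels - 1 predictors
    return np.column_stack([(values.astype(str) == lev).astype(float)
                            for lev in levels[1:]])


def pc_covariate_association(scores: np.ndarray, covariate: np.ndarray,
                             covariate_name: str = "covariate", pc_index: int = 0,
                             kind: str = "categorical") -> AssociationResult:
    """OLS of one PC on a covariate, reported as adjusted R-squared.

    The covariate is the predictor (dummy-encoded if categorical, integer
    codes if ordinal) and the PC score the response;
    R2_adj = 1 - (1 - R2)(n - 1)/(n - p - 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = scores[:, pc_index] if scores.ndim == 2 else scores
    X = _encode_covariate(np.asarray(covariate), kind)
    n, p = X.shape
    if n - p - 1 < 1:
        raise ValueError(f"adjusted R2 undefined: n={n}, p={p}")
    import statsmodels.api as sm

    fit = sm.OLS(y, sm.add_constant(X)).fit()
    r2 = float(fit.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return AssociationResult(covariate_name, pc_index, float(adj), r2, n, p)


def knn_sample_classifier(train: SampleEmbeddingMatrix, train_labels: np.ndarray,
                          test: SampleEmbeddingMatrix | None = None, k: int = 5,
                          n_folds: int = 5, seed: int = 0) -> dict:
    """kNN majority vote over Euclidean sample-embedding distances.

    Returns test predictions (if a test matrix is given) and stratified
    ``n_folds``-fold cross-validation accuracy / weighted F1 on the training
    conditions, as mean and standard error over folds.
    """
    from sklearn.metrics import accuracy_score, f1_score
    from sklearn.model_selection import StratifiedKFold
    from sklearn.neighbors import KNeighborsClassifier

    X = np.asarray(train.matrix, dtype=float)
    y = np.asarray(train_labels).astype(str)
    if k > len(y):
        raise ValueError("k exceeds the number of training conditions")
    out: dict = {}
    if test is not None:
        clf = KNeighborsClassifier(n_neighbors=k).fit(X, y)
        out["predictions"] = clf.predict(np.asarray(test.matrix, dtype=float))

    accs, f1s = [], []
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        kk = min(k, len(tr))
        clf = KNeighborsClassifier(n_neighbors=kk).fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        accs.append(accuracy_score(y[te], pred))
        f1s.append(f1_score(y[te], pred, average="weighted", zero_division=0))
    accs, f1s = np.asarray(accs), np.asarray(f1s)
    out.update({
        "cv_accuracy_mean": float(accs.mean()),
        "cv_accuracy_se": float(accs.std(ddof=1) / np.sqrt(n_folds)),
        "cv_weighted_f1_mean": float(f1s.mean()),
        "cv_weighted_f1_se": float(f1s.std(ddof=1) / np.sqrt(n_folds)),
    })
    return out


def pseudobulk_baseline(ds: ExpressionDataset, by: str) -> pd.DataFrame:
    """Per-condition mean of log1p counts — the sample-level baseline
    representation that competes with learned embeddings."""
    if by not in ds.condition_covariates:
        raise KeyError(f"covariate '{by}' not in dataset")
    x = np.log1p(ds.dense_counts())
    groups = np.asarray(ds.condition_covariates[by])
    names = sorted(np.unique(groups).tolist())
    rows = [x[groups == g].mean(axis=0) for g in names]
    return pd.DataFrame(rows, index=pd.Index(names, name=by), columns=ds.feature_ids)


def gene_pc_correlation(ds: ExpressionDataset, scores: np.ndarray, by: str,
                        pc_index: int = 0, p_cutoff: float = 0.01,
                        r_cutoff: float = 0.3) -> pd.DataFrame:
    """Pearson screen of per-sample mean expression against a PC.

    For every gene, correlates its per-sample log1p mean expression with the
    per-sample PC scores; genes pass at |r| > ``r_cutoff`` and two-sided
    p < ``p_cutoff``. Zero-variance genes are excluded (column ``excluded``).
    Sorted by r descending.
    """
    pseudo = pseudobulk_baseline(ds, by)
    scores = np.asarray(scores, dtype=float)
    s = scores[:, pc_index] if scores.ndim == 2 else scores
    if len(s) != len(pseudo):
        raise ValueError("scores length does not match number of conditions")
    if len(s) < 3:
        raise ValueError("need at least 3 samples for a correlation screen")
    rows = []
    for gene in pseudo.columns:
        expr = pseudo[gene].to_numpy()
        if np.ptp(expr) == 0:
            rows.append({"gene": gene, "r": np.nan, "p": np.nan,
                         "passed": False, "excluded": True})
            continue
        r, p = stats.pearsonr(expr, s)
        rows.append({"gene": gene, "r": float(r), "p": float(p),
                     "passed": bool((p < p_cutoff) and (abs(r) > r_cutoff)),
                     "excluded": False})
    df = pd.DataFrame(rows)
    return df.sort_values("r", ascending=False, na_position="last").reset_index(drop=True)
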