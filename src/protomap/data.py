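"""Count-matrix containers, readers/writers and the synthetic atlas generator.

The central container is :class:`ExpressionDataset`: a cells x features
non-negative integer count matrix together with named categorical condition
covariates (batch, sample, study, ...) and zero or more levels of cell-type
annotation in which individual cells may carry the :data:`UNLABELED`
sentinel. Cells are always rows and features columns; covariates and
annotations are addressed by name, never by position.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNLABELED = "__unlabeled__"

__all__ = [
    "UNLABELED",
    "ExpressionDataset",
    "SyntheticAtlasSpec",
    "load_dataset",
    "save_dataset",
    "select_hvgs",
    "generate_synthetic_atlas",
    "generate_planted_screen",
]


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


class ConfigurationError(KeyError):
    """Raised when a requested metadata key is absent."""


@dataclass
class ExpressionDataset:
    """Counts plus per-cell condition covariates and (partial) annotations.

    Parameters
    ----------
    counts
        ``(n_cells, n_features)`` non-negative integer matrix, dense or
        CSR/CSC sparse. Kept sparse if provided sparse.
    feature_ids, cell_ids
        Unique names for columns and rows.
    condition_covariates
        Ordered mapping covariate name -> per-cell category array. Order is
        meaningful: condition embeddings are concatenated in this order.
    annotations
        Ordered mapping annotation level name -> per-cell label array;
        entries may be :data:`UNLABELED`.
    """

    counts: np.ndarray | sp.spmatrix
    feature_ids: list[str]
    cell_ids: list[str]
    condition_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if sp.issparse(self.counts):
            self.counts = sp.csr_matrix(self.counts)
            self.counts.sum_duplicates()
            self.counts.eliminate_zeros()
            data = self.counts.data
        else:
            self.counts = np.asarray(self.counts)
            data = self.counts.ravel()
        if data.size and (np.min(data) < 0):
            bad = int(np.argmin(data))
            raise ValidationError(f"negative count at flat position {bad}")
        if data.size and not np.allclose(data, np.round(data)):
            bad = np.flatnonzero(~np.isclose(data, np.round(data)))[:5]
            raise ValidationError(f"non-integer counts at flat positions {bad.tolist()}")
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.feature_ids) != g:
            raise ValidationError("cell/feature id lengths do not match counts shape")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        for name, vec in {**self.condition_covariates, **self.annotations}.items():
            if len(np.asarray(vec, dtype=object)) != n:
                raise ValidationError(f"vector '{name}' has length {len(vec)}, expected {n}")
        # object arrays of python str: fixed-width U dtypes would truncate
        # longer labels (e.g. the UNLABELED sentinel) on later assignment
        as_str = lambda v: np.array([str(x) for x in np.asarray(v, dtype=object)],
                                    dtype=object)
        self.condition_covariates = {k: as_str(v) for k, v in self.condition_covariates.items()}
        self.annotations = {k: as_str(v) for k, v in self.annotations.items()}
        for name, vec in self.condition_covariates.items():
            if len(np.unique(vec)) < 1:
                raise ValidationError(f"covariate '{name}' has no levels")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def library_size(self) -> np.ndarray:
        """Per-cell total counts (row sums)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.sum(axis=1)).ravel().astype(float)
        return self.counts.sum(axis=1).astype(float)

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionDataset":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return ExpressionDataset(
            counts=self.counts[idx],
            feature_ids=list(self.feature_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            condition_covariates={k: v[idx] for k, v in self.condition_covariates.items()},
            annotations={k: v[idx] for k, v in self.annotations.items()},
        )

    def subset_features(self, idx: np.ndarray) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            feature_ids=[self.feature_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            condition_covariates=dict(self.condition_covariates),
            annotations=dict(self.annotations),
        )

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        for k, v in self.condition_covariates.items():
            obs[k] = pd.Categorical(v)
        for k, v in self.annotations.items():
            obs[k] = pd.Categorical(v)
        x = self.counts if sp.issparse(self.counts) else np.asarray(self.counts)
        adata = ad.AnnData(X=x, obs=obs)
        adata.var_names = pd.Index(self.feature_ids, name="feature_id")
        adata.uns["protomap"] = {
            "covariate_keys": list(self.condition_covariates),
            "annotation_keys": list(self.annotations),
        }
        return adata


def _meta_frame(ds: ExpressionDataset) -> pd.DataFrame:
    meta = pd.DataFrame(index=pd.Index(ds.cell_ids, name="cell_id"))
    for k, v in ds.condition_covariates.items():
        meta[k] = v
    for k, v in ds.annotations.items():
        meta[k] = v
    return meta


def save_dataset(ds: ExpressionDataset, path: str, format: str = "anndata") -> None:
    """Write a dataset as ``anndata`` (.h5ad), ``mtx_dir`` or ``delimited``.

    ``mtx_dir`` writes ``matrix.mtx`` (cells x features), ``cells.tsv``
    (cell_id + covariate/annotation columns) and ``features.tsv``.
    ``delimited`` writes a cells x features TSV plus a ``<path>.meta.tsv``
    sidecar when metadata is present. Round trips are exact.
    """
    if format == "anndata":
        ds.to_anndata().write_h5ad(path)
    elif format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        from scipy.io import mmwrite

        mat = ds.counts if sp.issparse(ds.counts) else sp.csr_matrix(ds.counts)
        mmwrite(os.path.join(path, "matrix.mtx"), mat, field="integer")
        _meta_frame(ds).to_csv(os.path.join(path, "cells.tsv"), sep="\t")
        pd.Series(ds.feature_ids, name="feature_id").to_csv(
            os.path.join(path, "features.tsv"), sep="\t", index=False
        )
    elif format == "delimited":
        df = pd.DataFrame(ds.dense_counts().astype(int), index=pd.Index(ds.cell_ids, name="cell_id"),
                          columns=ds.feature_ids)
        df.to_csv(path, sep="\t")
        if ds.condition_covariates or ds.annotations:
            _meta_frame(ds).to_csv(path + ".meta.tsv", sep="\t")
    else:
        raise ConfigurationError(f"unknown format '{format}'")


def load_dataset(path: str, format: str = "anndata",
                 covariate_keys: list[str] | None = None,
                 annotation_keys: list[str] | None = None) -> ExpressionDataset:
    """Read a dataset written by :func:`save_dataset` (or compatible files).

    ``covariate_keys`` / ``annotation_keys`` select metadata columns; a
    missing key raises :class:`ConfigurationError` naming it. Sparse inputs
    stay sparse.
    """
    covariate_keys = list(covariate_keys or [])
    annotation_keys = list(annotation_keys or [])

    if format == "anndata":
        import anndata as ad

        adata = ad.read_h5ad(path)
        meta = adata.obs
        counts = adata.X
        cell_ids = list(adata.obs_names)
        feature_ids = list(adata.var_names)
        if not covariate_keys and "protomap" in adata.uns:
            covariate_keys = list(adata.uns["protomap"].get("covariate_keys", []))
            annotation_keys = annotation_keys or list(
                adata.uns["protomap"].get("annotation_keys", []))
    elif format == "mtx_dir":
        from scipy.io import mmread

        counts = sp.csr_matrix(mmread(os.path.join(path, "matrix.mtx")))
        meta = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t", index_col=0, dtype=str)
        cell_ids = list(meta.index)
        feature_ids = list(pd.read_csv(os.path.join(path, "features.tsv"), sep="\t")["feature_id"].astype(str))
    elif format == "delimited":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        counts = df.to_numpy()
        cell_ids = list(df.index.astype(str))
        feature_ids = list(df.columns.astype(str))
        meta_path = str(path) + ".meta.tsv"
        meta = (pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
                if os.path.exists(meta_path) else pd.DataFrame(index=cell_ids))
    else:
        raise ConfigurationError(f"unknown format '{format}'")

    for key in covariate_keys + annotation_keys:
        if key not in meta.columns:
            raise ConfigurationError(f"metadata key '{key}' not found in {path}")
    return ExpressionDataset(
        counts=counts,
        feature_ids=feature_ids,
        cell_ids=cell_ids,
        condition_covariates={k: np.asarray(meta[k], dtype=object) for k in covariate_keys},
        annotations={k: np.asarray(meta[k], dtype=object) for k in annotation_keys},
    )


def select_hvgs(ds: ExpressionDataset, n_top: int, per_batch_key: str | None = None) -> ExpressionDataset:
    """Restrict to the ``n_top`` most highly variable features.

    Uses dispersion-based (Seurat-flavor) ranking on log-normalized counts,
    globally by default or batch-aware when ``per_batch_key`` names a
    covariate. Ranking is deterministic: ties in normalized dispersion break
    by original feature order.
    """
    if n_top > ds.n_features:
        raise ValidationError(f"n_top={n_top} exceeds n_features={ds.n_features}")
    if n_top == ds.n_features:
        return ds.subset_features(np.arange(ds.n_features))
    import scanpy as sc

    adata = ds.to_anndata()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top,
                                batch_key=per_batch_key)
    disp = np.asarray(adata.var["dispersions_norm"], dtype=float)
    disp = np.where(np.isfinite(disp), disp, -np.inf)
    # constant features carry no information regardless of their bin z-score
    variances = ds.dense_counts().var(axis=0)
    disp = np.where(variances > 0, disp, -np.inf)
    order = np.lexsort((np.arange(ds.n_features), -disp))
    keep = np.sort(order[:n_top])
    return ds.subset_features(keep)


@dataclass
class SyntheticAtlasSpec:
    """Parameters of the synthetic multi-batch atlas generator.

    Counts for a cell of type ``t`` in batch ``b`` are negative binomial with
    log-mean = baseline + type signature + batch shift. ``type_separation``
    and ``batch_effect_scale`` are the per-feature standard deviations of the
    type and batch effects on the log scale; ``dispersion`` is the NB
    inverse-dispersion (shape) shared by all features. The last
    ``n_query_batches`` batches form the query; ``held_out_types`` occur only
    there. Cohort fields optionally give groups of batches a shared shift
    direction, emulating e.g. assay or site effects at the sample level.
    """

    n_cell_types: int = 5
    n_batches: int = 6
    cells_per_batch: int = 650
    n_features: int = 200
    batch_effect_scale: float = 0.3
    type_separation: float = 1.5
    dispersion: float = 5.0
    fraction_unlabeled: float = 0.0
    held_out_types: frozenset = frozenset()
    n_query_batches: int = 2
    n_cohorts: int = 1
    cohort_effect_scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cell_types, self.n_batches, self.cells_per_batch, self.n_features) < 1:
            raise ValidationError("all counts must be >= 1")
        if not set(self.held_out_types) <= set(range(self.n_cell_types)):
            raise ValidationError("held_out_types must be a subset of type indices")
        if len(self.held_out_types) >= self.n_cell_types:
            raise ValidationError("held_out_types would leave the query without shared types")
        if not 0.0 <= self.fraction_unlabeled <= 1.0:
            raise ValidationError("fraction_unlabeled must lie in [0, 1]")
        if self.n_query_batches >= self.n_batches:
            raise ValidationError("need at least one reference batch")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB(mu, theta) via the Gamma-Poisson mixture; theta = inverse-dispersion."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def generate_synthetic_atlas(spec: SyntheticAtlasSpec):
    """Simulate a reference/query pair of multi-batch count datasets.

    Returns ``(reference, query, truth)`` where ``truth`` is the per-cell
    true type label for the query cells (reference truth is in its
    annotations before masking). Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    G, T, B = spec.n_features, spec.n_cell_types, spec.n_batches

    baseline = rng.normal(loc=0.0, scale=0.5, size=G)
    type_sig = rng.normal(scale=spec.type_separation, size=(T, G))
    cohort_of_batch = np.arange(B) % max(spec.n_cohorts, 1)
    cohort_dir = rng.normal(scale=1.0, size=(max(spec.n_cohorts, 1), G))
    batch_shift = rng.normal(scale=spec.batch_effect_scale, size=(B, G))
    batch_shift = batch_shift + spec.cohort_effect_scale * cohort_dir[cohort_of_batch]

    n_ref_batches = B - spec.n_query_batches
    held_out = sorted(spec.held_out_types)
    ref_types = [t for t in range(T) if t not in held_out]

    blocks = {"ref": ([], [], [], []), "query": ([], [], [], [])}  # counts, type, batch, ids
    for b in range(B):
        is_query = b >= n_ref_batches
        pool = list(range(T)) if is_query else ref_types
        types = rng.choice(pool, size=spec.cells_per_batch)
        logmu = baseline[None, :] + type_sig[types] + batch_shift[b][None, :]
        counts = _nb_sample(rng, np.exp(logmu), spec.dispersion)
        key = "query" if is_query else "ref"
        blocks[key][0].append(counts)
        blocks[key][1].append(types)
        blocks[key][2].append(np.full(spec.cells_per_batch, f"batch{b}", dtype=object))
        blocks[key][3].append([f"b{b}_c{i}" for i in range(spec.cells_per_batch)])

    features = [f"gene{g}" for g in range(G)]

    def _assemble(key: str, mask_fraction: float) -> tuple[ExpressionDataset, np.ndarray]:
        counts = np.vstack(blocks[key][0])
        types = np.concatenate(blocks[key][1])
        batches = np.concatenate(blocks[key][2])
        ids = [c for chunk in blocks[key][3] for c in chunk]
        labels = np.array([f"type{t}" for t in types], dtype=object)
        truth = labels.copy()
        if mask_fraction > 0:
            hide = rng.random(len(labels)) < mask_fraction
            labels[hide] = UNLABELED
        ds = ExpressionDataset(
            counts=sp.csr_matrix(counts),
            feature_ids=features,
            cell_ids=ids,
            condition_covariates={"sample": batches},
            annotations={"cell_type": labels},
        )
        return ds, truth

    reference, _ = _assemble("ref", spec.fraction_unlabeled)
    query, truth = _assemble("query", 1.0)  # query arrives unannotated
    return reference, query, truth


def generate_planted_screen(n_samples: int = 60, cells_per_sample: int = 30,
                            n_features: int = 1000, n_planted: int = 50,
                            effect: float = 0.4, seed: int = 0):
    """Synthetic per-sample screen for gene-covariate correlation analyses.

    Each sample j carries a scalar score s_j ~ N(0, 1); the first
    ``n_planted`` features have Poisson log-rates shifted by
    ``effect * s_j`` while the rest are null. Returns
    ``(dataset, scores_by_sorted_sample_name, planted_feature_ids)``.
    """
    rng = np.random.default_rng(seed)
    s = rng.normal(size=n_samples)
    beta = np.zeros(n_features)
    beta[:n_planted] = effect
    counts, samples = [], []
    for j in range(n_samples):
        lam = np.exp(np.log(2.0) + beta * s[j])
        counts.append(rng.poisson(lam, size=(cells_per_sample, n_features)))
        samples += [f"s{j:03d}"] * cells_per_sample
    features = [f"gene{g}" for g in range(n_features)]
    ds = ExpressionDataset(
        counts=np.vstack(counts),
        feature_ids=features,
        cell_ids=[f"c{i}" for i in range(n_samples * cells_per_sample)],
        condition_covariates={"sample": np.array(samples, dtype=object)},
    )
    return ds, s, features[:n_planted]
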