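"""Reference building and frozen-weight query-to-reference mapping.

Reference building runs in two phases. Pretraining optimizes the
conditional-VAE objective alone, with the KL weight linearly annealed from
zero. Fine-tuning (the final ``1 - pretrain_fraction`` of epochs, 0.1 by
default) initializes cell-type prototypes as per-label latent means and
optimizes L_CVAE + eta * L_prototype; prototypes are recomputed from the
current latent means at the start of every fine-tuning epoch and stored
with the model at the end, together with Louvain-cluster prototypes for any
unlabeled cells.

Query mapping freezes every encoder/decoder weight and every reference
condition embedding; the only trainable parameters are the fresh embedding
rows of the query conditions. Labeled query cells fine-tune against the
stored reference prototypes (new labels get new prototypes); a fully
unlabeled query reduces the objective to L_CVAE.
"""

from __future__ import annotations

import copy
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cvae import CVAEModel, LatentRepresentation, ModelConfig
from .data import UNLABELED, ExpressionDataset
from .nn import Adam
from .prototypes import (PrototypeSet, compute_labeled_prototypes,
                         compute_unlabeled_prototypes)

__all__ = ["TrainingReport", "build_reference", "map_query", "get_latent"]


@dataclass
class TrainingReport:
    """Per-epoch loss components; phase flips from pretrain to finetune once."""

    rows: list[dict] = field(default_factory=list)

    def log(self, **row) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _kl_weight(epoch: int, anneal_epochs: int) -> float:
    if anneal_epochs <= 0:
        return 1.0
    return min(1.0, (epoch + 1) / anneal_epochs)


def _epoch_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def _labeled_prototype_targets(model: CVAEModel, ds: ExpressionDataset,
                               latent_mean: np.ndarray,
                               frozen_sets: dict[str, PrototypeSet] | None = None,
                               provenance: str = "reference") -> dict[str, PrototypeSet]:
    """Per-level prototype sets from current latent means.

    When ``frozen_sets`` is given (query fine-tuning), labels already present
    there keep their stored vectors; only genuinely new labels get
    freshly computed prototypes.
    """
    sets: dict[str, PrototypeSet] = {}
    for level, ann in ds.annotations.items():
        mask = np.asarray(ann) != UNLABELED
        if not mask.any():
            continue
        fresh = compute_labeled_prototypes(latent_mean[mask], np.asarray(ann)[mask],
                                           level=level, provenance=provenance)
        if frozen_sets and level in frozen_sets:
            keep = {k: v for k, v in fresh.labeled.items()
                    if k not in frozen_sets[level].labeled}
            merged = PrototypeSet(level, {**frozen_sets[level].labeled, **keep},
                                  provenance=provenance)
            sets[level] = merged
        else:
            sets[level] = fresh
    return sets


def _run_phase(model: CVAEModel, ds: ExpressionDataset, epochs: range, phase: str,
               opt: Adam, rng: np.random.Generator, report: TrainingReport,
               eta: float, frozen_protos: dict[str, PrototypeSet] | None = None,
               provenance: str = "reference") -> dict[str, PrototypeSet]:
    x = ds.dense_counts()
    conds = {c: ds.condition_covariates[c] for c in model.covariate_order}
    idx_cache = {c: model.tables[c].index_of(conds[c]) for c in model.covariate_order}
    cfg = model.config
    proto_sets: dict[str, PrototypeSet] = {}
    for epoch in epochs:
        t0 = time.perf_counter()
        klw = _kl_weight(epoch, cfg.kl_anneal_epochs)
        proto_targets = None
        if phase == "finetune" and eta > 0 and ds.annotations:
            latent = get_latent(ds, model, mode="mean").mean
            proto_sets = _labeled_prototype_targets(model, ds, latent,
                                                    frozen_sets=frozen_protos,
                                                    provenance=provenance)
        acc = {"reconstruction": 0.0, "kl": 0.0, "prototype": 0.0}
        n_seen = 0
        for mb in _epoch_minibatches(ds.n_cells, cfg.batch_size, rng):
            mb_conds = {c: np.asarray(conds[c])[mb] for c in model.covariate_order}
            targets = None
            if proto_sets:
                targets = []
                for level, ps in proto_sets.items():
                    assign = ps.assignment_index(np.asarray(ds.annotations[level])[mb])
                    targets.append((ps.matrix(), assign))
            comps, grads = model.loss_and_grads(
                x[mb], mb_conds, kl_weight=klw, rng=rng, sample=True,
                proto_targets=targets, eta=eta if phase == "finetune" else 0.0)
            _apply_step(model, opt, grads)
            w = len(mb)
            for k in acc:
                acc[k] += comps[k] * w
            n_seen += w
        report.log(epoch=epoch, phase=phase,
                   reconstruction=acc["reconstruction"] / n_seen,
                   kl=acc["kl"] / n_seen, prototype=acc["prototype"] / n_seen,
                   kl_weight=klw, seconds=time.perf_counter() - t0)
    return proto_sets


def _apply_step(model: CVAEModel, opt: Adam, grads: dict) -> None:
    full = dict(model.params)
    for cov in model.covariate_order:
        full[f"emb.{cov}"] = model.tables[cov].matrix
    opt.step(full, grads)
    for k in model.params:
        model.params[k] = full[k]
    for cov in model.covariate_order:
        model.tables[cov].matrix = full[f"emb.{cov}"]


def _store_prototypes(model: CVAEModel, ds: ExpressionDataset, eta: float,
                      frozen_protos: dict[str, PrototypeSet] | None = None,
                      provenance: str = "reference",
                      cluster_seed: int = 0) -> None:
    """Final labeled + unlabeled prototypes computed from the trained model."""
    latent = get_latent(ds, model, mode="mean").mean
    for level, ann in ds.annotations.items():
        ann = np.asarray(ann)
        labeled_mask = ann != UNLABELED
        parts = []
        if labeled_mask.any():
            sets = _labeled_prototype_targets(model, ds, latent,
                                              frozen_sets=frozen_protos,
                                              provenance=provenance)
            parts.append(sets[level])
        if (~labeled_mask).any():
            parts.append(compute_unlabeled_prototypes(
                latent[~labeled_mask], level=level, seed=cluster_seed,
                provenance=provenance))
        if not parts:
            continue
        merged = parts[0]
        for extra in parts[1:]:
            merged = merged.merged_with(extra)
        if frozen_protos and level in frozen_protos:
            merged = merged.merged_with(frozen_protos[level])
        model.prototypes[level] = merged


def build_reference(ds: ExpressionDataset, config: ModelConfig,
                    n_epochs: int = 100) -> tuple[CVAEModel, TrainingReport]:
    """Train a reference model: CVAE pretraining then prototype fine-tuning."""
    if not ds.condition_covariates:
        raise ValueError("reference dataset needs at least one condition covariate")
    eta = config.prototype_loss_weight
    any_labeled = any((np.asarray(a) != UNLABELED).any() for a in ds.annotations.values())
    if eta > 0 and not any_labeled:
        if ds.annotations:
            warnings.warn("no labeled cells: prototype loss disabled, training plain CVAE")
        eta = 0.0

    covariates = {c: sorted(np.unique(v).tolist())
                  for c, v in ds.condition_covariates.items()}
    model = CVAEModel.create(config, ds.feature_ids, covariates)
    rng = np.random.default_rng([config.seed, 7])
    opt = Adam(model.all_trainable(), lr=config.learning_rate)
    report = TrainingReport()

    n_pre = int(np.ceil(config.pretrain_fraction * n_epochs))
    _run_phase(model, ds, range(n_pre), "pretrain", opt, rng, report, eta)
    _run_phase(model, ds, range(n_pre, n_epochs), "finetune", opt, rng, report, eta)
    _store_prototypes(model, ds, eta, provenance="reference", cluster_seed=config.seed)
    return model, report


def map_query(reference_state: CVAEModel, query: ExpressionDataset,
              n_epochs: int = 100) -> tuple[CVAEModel, TrainingReport]:
    """Integrate query data by training only new condition embeddings.

    Encoder, decoder and reference embeddings are frozen bitwise; M new
    embedding rows (one per unseen query condition) are the sole trainable
    parameters. Labeled query cells fine-tune against the stored reference
    prototypes; new labels extend the prototype set.
    """
    if list(query.feature_ids) != list(reference_state.feature_ids):
        missing = sorted(set(reference_state.feature_ids) - set(query.feature_ids))
        raise ValueError(f"feature set mismatch with reference; missing: {missing[:10]}")
    if list(query.condition_covariates) != list(reference_state.covariate_order):
        raise ValueError(
            f"covariate structure mismatch: reference uses {reference_state.covariate_order}, "
            f"query provides {list(query.condition_covariates)}")

    model = copy.deepcopy(reference_state)
    cfg = model.config
    rng = np.random.default_rng([cfg.seed, 11])
    for cov in model.covariate_order:
        levels = sorted(np.unique(query.condition_covariates[cov]).tolist())
        model.tables[cov].extend(levels, rng, freeze_existing=True)
    model.frozen = set(model.network_param_names)

    eta = cfg.prototype_loss_weight
    any_labeled = any((np.asarray(a) != UNLABELED).any() for a in query.annotations.values())
    if not any_labeled:
        eta = 0.0

    opt = Adam(model.all_trainable(embeddings_only=True), lr=cfg.learning_rate)
    report = TrainingReport()
    frozen_protos = {lvl: ps for lvl, ps in reference_state.prototypes.items()}
    n_pre = int(np.ceil(cfg.pretrain_fraction * n_epochs))
    _run_phase(model, query, range(n_pre), "pretrain", opt, rng, report, eta,
               provenance="query")
    _run_phase(model, query, range(n_pre, n_epochs), "finetune", opt, rng, report,
               eta, frozen_protos=frozen_protos, provenance="query")
    _store_prototypes(model, query, eta, frozen_protos=frozen_protos,
                      provenance="query", cluster_seed=cfg.seed)
    return model, report


def get_latent(ds: ExpressionDataset, state: CVAEModel, mode: str = "mean",
               chunk: int = 4096, rng: np.random.Generator | None = None) -> LatentRepresentation:
    """Latent representation of every cell; ``mean`` mode is deterministic."""
    x = ds.dense_counts()
    conds = {c: np.asarray(ds.condition_covariates[c]) for c in state.covariate_order}
    means, lvs, zs = [], [], []
    for start in range(0, ds.n_cells, chunk):
        sl = slice(start, start + chunk)
        rep = state.encode(x[sl], {c: v[sl] for c, v in conds.items()},
                           mode=mode, rng=rng)
        means.append(rep.mean)
        lvs.append(rep.logvar)
        zs.append(rep.z)
    return LatentRepresentation(np.vstack(means), np.vstack(lvs), np.vstack(zs))
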