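"""Conditional VAE with learnable condition embeddings.

The model is a standard count-data conditional VAE in which every level of a
batch covariate (sample, study, assay, ...) is represented by a trainable
vector of dimension E instead of a one-hot indicator: the embedding vectors
are concatenated to the (log1p-transformed) expression input of the encoder
and to the latent vector at the decoder input, and are optimized jointly
with the network weights by minimizing the evidence lower bound

    L(theta, phi, s) = -E_q[log p(x | z, c)] + D_KL(q(z | x, c) || N(0, I)).

The reconstruction term is the negative log-likelihood of a negative
binomial (RNA counts) or Poisson (fragment counts) distribution whose mean
is the decoder's per-cell simplex over features scaled by the observed
library size. With E equal to the number of conditions and the embedding
table fixed to the identity matrix, the input layer reproduces a one-hot
conditioned CVAE exactly.

All networks are narrow MLPs computed in numpy with explicit
backpropagation (see :mod:`protomap.nn`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .nn import MLP, Dense
from . import prototypes as proto_mod

LOGVAR_CLIP = 12.0
_EPS = 1e-12

__all__ = [
    "ModelConfig",
    "ConditionEmbeddingTable",
    "LatentRepresentation",
    "LikelihoodParams",
    "CVAEModel",
    "nb_negative_log_likelihood",
    "poisson_negative_log_likelihood",
    "kl_divergence",
    "count_trainable_parameters",
    "fewer_parameters_than_onehot",
]


@dataclass
class ModelConfig:
    """Hyperparameters of the conditional VAE.

    ``hidden_width="auto"`` sets the hidden layer width to the square root
    of the input feature count (rounded). ``prototype_loss_weight`` is the
    weight eta of the supervised prototype term during fine-tuning and
    ``minkowski_p`` the order of the distance it uses. ``pretrain_fraction``
    splits total epochs into unsupervised pretraining and supervised
    fine-tuning (default 0.9).
    """

    embedding_dim: int = 5
    latent_dim: int = 10
    encoder_depth: int = 1
    decoder_depth: int = 1
    hidden_width: int | str = "auto"
    likelihood: str = "negative_binomial"
    prototype_loss_weight: float = 1.0
    minkowski_p: float = 2.0
    kl_anneal_epochs: int = 10
    learning_rate: float = 1e-3
    pretrain_fraction: float = 0.9
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.embedding_dim < 1 or self.latent_dim < 1:
            raise ValueError("embedding_dim and latent_dim must be >= 1")
        if self.prototype_loss_weight < 0:
            raise ValueError("prototype_loss_weight must be >= 0")
        if not 0.0 <= self.pretrain_fraction <= 1.0:
            raise ValueError("pretrain_fraction must lie in [0, 1]")
        if self.likelihood not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown likelihood '{self.likelihood}'")

    def resolve_width(self, n_features: int) -> int:
        if self.hidden_width == "auto":
            return max(int(round(np.sqrt(n_features))), 2)
        return int(self.hidden_width)


class ConditionEmbeddingTable:
    """Ordered map condition name -> E-vector for one covariate.

    Rows with index below ``n_frozen`` belong to the reference and never
    change during query training.
    """

    def __init__(self, covariate: str, names: list[str], dim: int, rng: np.random.Generator):
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate condition names in covariate '{covariate}'")
        self.covariate = covariate
        self.names = list(names)
        self.dim = dim
        # random init, scaled so vectors have unit expected norm
        self.matrix = rng.standard_normal((len(names), dim)) / np.sqrt(dim)
        self.n_frozen = 0

    def index_of(self, conditions: np.ndarray) -> np.ndarray:
        lut = {n: i for i, n in enumerate(self.names)}
        try:
            return np.array([lut[str(c)] for c in conditions], dtype=int)
        except KeyError as exc:
            raise LookupError(
                f"unknown condition {exc} for covariate '{self.covariate}'") from None

    def extend(self, new_names: list[str], rng: np.random.Generator, freeze_existing: bool = True):
        """Add rows for query conditions, freezing the existing ones."""
        if freeze_existing:
            self.n_frozen = len(self.names)
        added = [n for n in new_names if n not in self.names]
        if added:
            extra = rng.standard_normal((len(added), self.dim)) / np.sqrt(self.dim)
            self.matrix = np.vstack([self.matrix, extra])
            self.names.extend(added)


@dataclass
class LatentRepresentation:
    """Per-cell variational posterior: mean, log-variance and a sample z."""

    mean: np.ndarray
    logvar: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        for a in (self.mean, self.logvar, self.z):
            if not np.all(np.isfinite(a)):
                raise ValueError("latent representation contains non-finite values")


@dataclass
class LikelihoodParams:
    """Decoder output distribution parameters.

    NB: per-cell per-feature mean ``mu`` and per-feature inverse-dispersion
    ``alpha``; Poisson: per-cell per-feature rate ``lam``.
    """

    mu: np.ndarray | None = None
    alpha: np.ndarray | None = None
    lam: np.ndarray | None = None


def nb_negative_log_likelihood(x: np.ndarray, params: LikelihoodParams) -> np.ndarray:
    """Per-cell NB negative log-likelihood, summed over features.

    Gamma-function form with mean mu and inverse-dispersion alpha (variance
    mu + mu^2/alpha).
    """
    mu, alpha = params.mu, params.alpha
    if mu is None or alpha is None or np.any(alpha <= 0) or np.any(mu < 0):
        raise ValueError("NB likelihood requires mu >= 0 and alpha > 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    mu = np.maximum(mu, _EPS)
    logp = (gammaln(x + alpha) - gammaln(alpha) - gammaln(x + 1.0)
            + alpha * (np.log(alpha) - np.log(alpha + mu))
            + x * (np.log(mu) - np.log(alpha + mu)))
    return -logp.sum(axis=-1)


def poisson_negative_log_likelihood(x: np.ndarray, params: LikelihoodParams) -> np.ndarray:
    """Per-cell Poisson negative log-likelihood, summed over features."""
    lam = params.lam
    if lam is None or np.any(lam < 0):
        raise ValueError("Poisson likelihood requires lam >= 0")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    logp = x * np.log(np.maximum(lam, _EPS)) - lam - gammaln(x + 1.0)
    logp = np.where((x == 0) & (lam == 0), 0.0, logp)
    return -logp.sum(axis=-1)


def kl_divergence(latent: LatentRepresentation) -> np.ndarray:
    """Closed-form per-cell KL(q(z|x,c) || N(0, I)), always >= 0."""
    mu, lv = latent.mean, latent.logvar
    return 0.5 * (mu ** 2 + np.exp(lv) - 1.0 - lv).sum(axis=-1)


def count_trainable_parameters(config: ModelConfig, n_features: int, n_conditions: int,
                               mode: str = "scpoli") -> int:
    """Parameters in which the embedding and one-hot variants differ.

    Counts the condition-embedding matrix (E x N) plus the encoder input
    layer ((G+E) x H_enc) and decoder input layer ((D+E) x H_dec) for the
    embedding variant, versus (G+N) x H_enc and (D+N) x H_dec for the
    one-hot variant; bias terms and the (identical) deeper layers are
    excluded. The embedding variant is smaller exactly when
    E < N*H/(N+H) with H = H_enc + H_dec.
    """
    G, N = n_features, n_conditions
    E, D = config.embedding_dim, config.latent_dim
    H_enc = H_dec = config.resolve_width(G)
    if mode == "scpoli":
        return E * N + (G + E) * H_enc + (D + E) * H_dec
    if mode == "onehot_cvae":
        return (G + N) * H_enc + (D + N) * H_dec
    raise ValueError(f"unknown mode '{mode}'")


def fewer_parameters_than_onehot(config: ModelConfig, n_features: int, n_conditions: int) -> bool:
    return (count_trainable_parameters(config, n_features, n_conditions, "scpoli")
            < count_trainable_parameters(config, n_features, n_conditions, "onehot_cvae"))


class CVAEModel:
    """Model state: encoder/decoder weights, embedding tables, prototypes.

    Construct with :meth:`create`, or restore a saved archive with
    :meth:`load`. ``frozen`` lists parameter names excluded from training
    (encoder/decoder weights after reference building).
    """

    FORMAT_VERSION = 1

    def __init__(self, config: ModelConfig, feature_ids: list[str],
                 covariate_order: list[str], tables: dict[str, ConditionEmbeddingTable],
                 rng: np.random.Generator):
        self.config = config
        self.feature_ids = list(feature_ids)
        self.covariate_order = list(covariate_order)
        self.tables = tables
        G = len(feature_ids)
        D = config.latent_dim
        H = config.resolve_width(G)
        e_total = sum(t.dim for t in tables.values())
        self.encoder = MLP("enc", G + e_total, H, config.encoder_depth, rng)
        self.mu_head = Dense("enc.mu", self.encoder.n_out, D, rng)
        self.lv_head = Dense("enc.lv", self.encoder.n_out, D, rng)
        self.decoder = MLP("dec", D + e_total, H, config.decoder_depth, rng)
        self.out_head = Dense("dec.out", self.decoder.n_out, G, rng)
        self.params: dict[str, np.ndarray] = {}
        for part in (self.encoder, self.mu_head, self.lv_head, self.decoder, self.out_head):
            self.params.update(part.params)
        if config.likelihood == "negative_binomial":
            self.params["dec.log_alpha"] = np.zeros(G)
        self.frozen: set[str] = set()
        self.prototypes: dict[str, proto_mod.PrototypeSet] = {}

    # ------------------------------------------------------------------ #
    @classmethod
    def create(cls, config: ModelConfig, feature_ids: list[str],
               covariates: dict[str, list[str]]) -> "CVAEModel":
        """Fresh model for the given features and covariate vocabularies."""
        rng = np.random.default_rng(config.seed)
        tables = {name: ConditionEmbeddingTable(name, levels, config.embedding_dim, rng)
                  for name, levels in covariates.items()}
        return cls(config, feature_ids, list(covariates), tables, rng)

    @property
    def network_param_names(self) -> list[str]:
        return [k for k in self.params if not k.startswith("emb.")]

    def embedding_matrix(self, covariate: str) -> np.ndarray:
        return self.tables[covariate].matrix

    # ------------------------------------------------------------------ #
    def _condition_indices(self, conditions: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        idx = {}
        for cov in self.covariate_order:
            if cov not in conditions:
                raise LookupError(f"covariate '{cov}' missing from conditions")
            idx[cov] = self.tables[cov].index_of(np.asarray(conditions[cov]))
        return idx

    def build_encoder_input(self, x: np.ndarray, conditions: dict[str, np.ndarray]) -> np.ndarray:
        """log1p-transformed counts concatenated with the embedding vectors,
        one block per covariate in declaration order."""
        idx = self._condition_indices(conditions)
        parts = [np.log1p(np.asarray(x, dtype=float))]
        parts += [self.tables[cov].matrix[idx[cov]] for cov in self.covariate_order]
        return np.concatenate(parts, axis=1)

    def encode(self, x: np.ndarray, conditions: dict[str, np.ndarray],
               mode: str = "mean", rng: np.random.Generator | None = None) -> LatentRepresentation:
        """Variational posterior for each cell; z = mean unless mode='sample'."""
        h = self.encoder.forward(self.params, self.build_encoder_input(x, conditions), cache=False)
        mu = self.mu_head.forward(self.params, h, cache=False)
        lv = np.clip(self.lv_head.forward(self.params, h, cache=False), -LOGVAR_CLIP, LOGVAR_CLIP)
        if mode == "sample":
            rng = rng or np.random.default_rng(self.config.seed)
            z = mu + np.exp(0.5 * lv) * rng.standard_normal(mu.shape)
        else:
            z = mu
        return LatentRepresentation(mean=mu, logvar=lv, z=z)

    def decode(self, z: np.ndarray, conditions: dict[str, np.ndarray],
               library_size: np.ndarray) -> LikelihoodParams:
        """Distribution parameters; means are a simplex over features scaled
        by the observed library size, so NB mu rows sum to the library size."""
        idx = self._condition_indices(conditions)
        parts = [np.asarray(z, dtype=float)]
        parts += [self.tables[cov].matrix[idx[cov]] for cov in self.covariate_order]
        h = self.decoder.forward(self.params, np.concatenate(parts, axis=1), cache=False)
        logits = self.out_head.forward(self.params, h, cache=False)
        f = _softmax(logits)
        lib = np.asarray(library_size, dtype=float).reshape(-1, 1)
        mean = lib * f
        if self.config.likelihood == "negative_binomial":
            return LikelihoodParams(mu=mean, alpha=np.exp(self.params["dec.log_alpha"]))
        return LikelihoodParams(lam=mean)

    # ------------------------------------------------------------------ #
    def loss_and_grads(self, x: np.ndarray, conditions: dict[str, np.ndarray],
                       kl_weight: float = 1.0, rng: np.random.Generator | None = None,
                       sample: bool = True,
                       proto_targets: list[tuple[np.ndarray, np.ndarray]] | None = None,
                       eta: float | None = None,
                       compute_grads: bool = True):
        """One forward/backward pass on a minibatch.

        ``proto_targets`` is a list of ``(P, assign)`` pairs, one per
        annotation level: ``P`` the (K, D) prototype matrix and ``assign``
        per-cell row indices into it, -1 for unlabeled cells. Returns
        ``(components, grads)`` where components holds the mean
        reconstruction NLL, mean KL, prototype loss and total.
        """
        x = np.asarray(x, dtype=float)
        n = x.shape[0]
        eta = self.config.prototype_loss_weight if eta is None else eta
        idx = self._condition_indices(conditions)
        emb_rows = [self.tables[cov].matrix[idx[cov]] for cov in self.covariate_order]
        xin = np.concatenate([np.log1p(x)] + emb_rows, axis=1)

        h = self.encoder.forward(self.params, xin)
        mu_z = self.mu_head.forward(self.params, h)
        lv_raw = self.lv_head.forward(self.params, h)
        lv = np.clip(lv_raw, -LOGVAR_CLIP, LOGVAR_CLIP)
        lv_mask = (lv_raw > -LOGVAR_CLIP) & (lv_raw < LOGVAR_CLIP)
        if sample:
            rng = rng or np.random.default_rng(self.config.seed)
            eps = rng.standard_normal(mu_z.shape)
        else:
            eps = np.zeros_like(mu_z)
        sig = np.exp(0.5 * lv)
        z = mu_z + sig * eps

        din = np.concatenate([z] + emb_rows, axis=1)
        hd = self.decoder.forward(self.params, din)
        logits = self.out_head.forward(self.params, hd)
        f = _softmax(logits)
        lib = x.sum(axis=1, keepdims=True)
        lib = np.maximum(lib, 1.0)
        mean = lib * f

        if self.config.likelihood == "negative_binomial":
            alpha = np.exp(self.params["dec.log_alpha"])
            recon = nb_negative_log_likelihood(x, LikelihoodParams(mu=mean, alpha=alpha))
        else:
            recon = poisson_negative_log_likelihood(x, LikelihoodParams(lam=mean))
        kl = 0.5 * (mu_z ** 2 + np.exp(lv) - 1.0 - lv).sum(axis=1)

        proto_loss = 0.0
        proto_grad_mu = np.zeros_like(mu_z)
        p_ord = self.config.minkowski_p
        if proto_targets and eta > 0:
            for P, assign in proto_targets:
                labeled = np.flatnonzero(np.asarray(assign) >= 0)
                if labeled.size == 0:
                    continue
                diff = mu_z[labeled] - P[np.asarray(assign)[labeled]]
                ad = np.abs(diff)
                dist = (ad ** p_ord).sum(axis=1) ** (1.0 / p_ord)
                proto_loss += dist.sum() / n
                safe = np.maximum(dist, _EPS) ** (p_ord - 1.0)
                proto_grad_mu[labeled] += (ad ** (p_ord - 1.0) * np.sign(diff)
                                           / safe[:, None]) / n

        total = recon.mean() + kl_weight * kl.mean() + eta * proto_loss
        components = {
            "reconstruction": float(recon.mean()),
            "kl": float(kl.mean()),
            "prototype": float(proto_loss),
            "kl_weight": float(kl_weight),
            "total": float(total),
        }
        if not np.isfinite(total):
            raise FloatingPointError("training diverged: non-finite loss")
        if not compute_grads:
            return components, None

        grads: dict[str, np.ndarray] = {}
        # --- reconstruction backward (mean over cells) ---
        if self.config.likelihood == "negative_binomial":
            mu_s = np.maximum(mean, _EPS)
            g_mu = (-(x / mu_s) + (x + alpha) / (alpha + mu_s)) / n
            dl_dalpha = -(digamma(x + alpha) - digamma(alpha)
                          + np.log(alpha) + 1.0 - np.log(alpha + mu_s)
                          - (alpha + x) / (alpha + mu_s))
            grads["dec.log_alpha"] = (dl_dalpha.sum(axis=0) / n) * alpha
        else:
            lam_s = np.maximum(mean, _EPS)
            g_mu = (1.0 - x / lam_s) / n
        a = g_mu * lib
        g_logits = f * (a - (a * f).sum(axis=1, keepdims=True))
        g_hd = self.out_head.backward(self.params, grads, g_logits)
        g_din = self.decoder.backward(self.params, grads, g_hd)
        D = self.config.latent_dim
        g_z = g_din[:, :D]
        g_emb_dec = g_din[:, D:]

        # --- KL backward ---
        g_mu_z = g_z + kl_weight * mu_z / n + eta * proto_grad_mu
        g_lv = (g_z * eps * 0.5 * sig + kl_weight * 0.5 * (np.exp(lv) - 1.0) / n) * lv_mask
        g_h = (self.mu_head.backward(self.params, grads, g_mu_z)
               + self.lv_head.backward(self.params, grads, g_lv))
        g_xin = self.encoder.backward(self.params, grads, g_h)
        G = len(self.feature_ids)
        g_emb_enc = g_xin[:, G:]

        # --- embedding-table gradients (encoder + decoder sides) ---
        off = 0
        for cov in self.covariate_order:
            dim = self.tables[cov].dim
            rows = g_emb_enc[:, off:off + dim] + g_emb_dec[:, off:off + dim]
            gE = np.zeros_like(self.tables[cov].matrix)
            np.add.at(gE, idx[cov], rows)
            gE[:self.tables[cov].n_frozen] = 0.0
            grads[f"emb.{cov}"] = gE
            off += dim
        return components, grads

    # ------------------------------------------------------------------ #
    def all_trainable(self, embeddings_only: bool = False) -> set[str]:
        names = {f"emb.{cov}" for cov in self.covariate_order}
        if not embeddings_only:
            names |= {k for k in self.params if k not in self.frozen}
        return names

    # ------------------------------------------------------------------ #
    def save(self, path: str) -> None:
        """Single-archive serialization; load() reproduces forward bitwise."""
        meta = {
            "format_version": self.FORMAT_VERSION,
            "config": dataclasses.asdict(self.config),
            "feature_ids": self.feature_ids,
            "covariate_order": self.covariate_order,
            "covariates": {c: self.tables[c].names for c in self.covariate_order},
            "n_frozen": {c: self.tables[c].n_frozen for c in self.covariate_order},
            "frozen": sorted(self.frozen),
            "prototype_levels": list(self.prototypes),
        }
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        for cov in self.covariate_order:
            arrays[f"emb::{cov}"] = self.tables[cov].matrix
        proto_meta = {}
        for level, ps in self.prototypes.items():
            labs, mat, unl = ps.to_arrays()
            arrays[f"proto::{level}"] = mat
            proto_meta[level] = {"labels": labs, "unlabeled_flags": unl,
                                 "provenance": ps.provenance}
        meta["prototypes"] = proto_meta
        np.savez(path, __meta__=np.array([json.dumps(meta)]), **arrays)

    @classmethod
    def load(cls, path: str) -> "CVAEModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"][0]))
            cfg = ModelConfig(**meta["config"])
            model = cls.create(cfg, meta["feature_ids"],
                               {c: meta["covariates"][c] for c in meta["covariate_order"]})
            for k in list(model.params):
                model.params[k] = npz[f"param::{k}"].copy()
            for cov in meta["covariate_order"]:
                model.tables[cov].matrix = npz[f"emb::{cov}"].copy()
                model.tables[cov].n_frozen = meta["n_frozen"][cov]
            model.frozen = set(meta["frozen"])
            for level, pm in meta["prototypes"].items():
                model.prototypes[level] = proto_mod.PrototypeSet.from_arrays(
                    level, pm["labels"], npz[f"proto::{level}"],
                    pm["unlabeled_flags"], pm["provenance"])
        return model


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)
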