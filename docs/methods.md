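# Methods

## Model

`protomap` integrates multi-batch single-cell count data with a conditional
variational autoencoder (CVAE) in which each level of a batch covariate
(sample, study, assay, ...) is represented by a *learnable condition
embedding* `s ∈ R^E` rather than a one-hot indicator. The embeddings are
concatenated to the encoder input and to the latent vector at the decoder
input, and are trained jointly with the network weights by minimizing the
evidence lower bound

```
L_CVAE(θ, φ, s) = −E_{z∼q_{φ,s}(z|x,c)} log p_{θ,s}(x|z,c)
                  + D_KL(q_{φ,s}(z|x,c) ‖ N(0, I)).
```

With several covariates, one embedding per covariate is looked up and the
blocks are concatenated in covariate declaration order; the order is stored
with the model so query mapping is consistent.

**Likelihoods.** The reconstruction term is the negative log-likelihood of
a negative binomial NB(μ, α) for RNA counts (α is the inverse-dispersion;
variance μ + μ²/α) or a Poisson(λ) for fragment counts (the natural choice
for scATAC-seq-style data). The decoder emits a per-cell simplex over
features (softmax output) which is scaled by the observed library size to
give μ (or λ), so predicted means always sum to the cell's total counts;
α is one free positive parameter per feature (`exp(log_alpha)`).

**Prototypes.** Cell identities are summarized by prototypes: the mean
latent vector of the cells carrying a label,
`p_k = mean_{i: a_i = k} z_i`. During fine-tuning a supervised term pulls
labeled cells toward their own prototype,

```
L_prototype = (1/N) Σ_l Σ_k Σ_i 1[a_i^(l) = k] · d(z_i, p_k^(l)),
```

where `d` is the Minkowski distance of order p (default 2, Euclidean) and
N is the minibatch size (all cells, labeled or not — the normalization
sits outside every sum). Multiple annotation levels contribute additively.
Cells with the UNLABELED sentinel are clustered with Louvain community
detection on a k-nearest-neighbor graph of the latent space (k = 15,
resolution 1.0) and summarized by *unlabeled* prototypes; these support
downstream annotation but never enter the loss.

**Label transfer.** A query cell takes the label of its nearest labeled
prototype; the minimizing distance is the cell's uncertainty `u_i`, which
has no upper bound but can be min-max scaled to [0, 1]. Cells with
uncertainty above a population quantile (default 0.9, computed over the
classified query population) are flagged unknown — candidates for cell
types absent from the reference. Ties in the argmin break to the
lexicographically smallest label for cross-platform determinism. Both
prototype computation and classification use the posterior mean μ_z, not a
sample, so transfer is deterministic.

**Parameter counting.** Replacing one-hot indicators by embeddings changes
the parameter count by the embedding matrix (E×N) and the encoder/decoder
input layers ((G+E)×H_enc + (D+E)×H_dec versus (G+N)×H_enc + (D+N)×H_dec).
Ignoring biases, the embedding variant is smaller exactly when
E < N·H/(N+H) with H = H_enc + H_dec; `count_trainable_parameters`
implements the two counts and the tests confirm the crossover by direct
counting, including against the instantiated network's array sizes.

## Training procedure

Reference building runs two phases under one Adam optimizer
(learning rate 0.001):

1. **Pretraining** (fraction 0.9 of epochs): L_CVAE alone, with the KL
   weight annealed linearly from 0 to 1 over `kl_anneal_epochs` (default
   10) epochs.
2. **Fine-tuning**: labeled prototypes are initialized as per-label latent
   means and L_CVAE + η·L_prototype is optimized (η default 1.0).
   Prototypes are recomputed from the current latent means at the start of
   every fine-tuning epoch and frozen within the epoch; gradients flow to
   z only, never through the stored prototype coordinates. Final
   prototypes (labeled + Louvain clusters of unlabeled cells) are stored
   with the model.

Query mapping freezes every encoder/decoder weight and every reference
embedding row bitwise; fresh embedding rows for the query conditions are
the only trainable parameters (a fresh optimizer guarantees frozen entries
never move). Labeled query cells fine-tune against the stored reference
prototypes — reference prototypes stay frozen, genuinely new labels get
new prototypes, enabling reference extension without retraining. A fully
unlabeled query reduces the objective to L_CVAE. Because weights and
reference embeddings are frozen, every reference cell's latent coordinate
is bitwise identical before and after mapping.

All stochasticity (parameter init, minibatch shuffling, reparameterization
noise, clustering) derives from the single config seed, so identical
seed + config reproduces identical reports, latents and predictions.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| latent dim D | 10 | typical for count VAEs at desk scale |
| embedding dim E | 5 | below the parameter-crossover threshold for realistic N |
| hidden width | √G (rounded) | standard heuristic tying capacity to input size |
| encoder/decoder depth | 1 | narrow data; deeper nets gain nothing at these sizes |
| likelihood | negative binomial | overdispersed RNA counts |
| η (prototype weight) | 1.0 | mid-grid value; the pull term is already on the per-cell scale |
| Minkowski order p | 2 | Euclidean; order 1 (Manhattan) available |
| KL anneal epochs | 10 | short ramp avoids early posterior collapse |
| pretrain fraction | 0.9 | 90/10 pretrain/fine-tune split |
| batch size | 256 | minibatch SGD default |
| learning rate | 0.001 | Adam default for this model family |

The encoder consumes log1p-transformed counts while the likelihood is
evaluated on raw counts — the standard stabilization for count VAEs; the
NB dispersion is per-feature (not per-condition or global). Hidden blocks
are Dense → per-sample layer normalization → ReLU; layer normalization is
used precisely because its statistics do not leak across cells in a batch.
Log-variances are clipped to ±12 as a numeric guard. All computation is
float64 numpy with explicit backpropagation; gradients of every parameter
group are verified against central finite differences in the test suite.

## Synthetic data

`generate_synthetic_atlas` emulates the structure the method assumes:
shared cell types across batches plus batch-specific technical shifts.
Counts for a cell of type t in batch b are NB with
`log μ = baseline_g + type_sig[t, g] + batch_shift[b, g]`, where the type
signature and batch shift are Gaussian per feature with standard
deviations `type_separation` and `batch_effect_scale`. Optional cohort
fields give groups of batches a shared shift direction, emulating
assay/site effects at the sample level. The last `n_query_batches` batches
form the query (delivered unannotated, with truth returned separately);
held-out types occur only there.

Default study conditions: 5 cell types, 4 reference + 2 query batches,
650 cells per batch (~3,900 cells), 200 features, type separation 1.5,
batch effect 0.3 (separation = 5× batch effect), NB inverse-dispersion 5.
The novel-type scenario uses 10 types with one held out, so novel cells
are ~10% of the query and the 90% uncertainty quantile matches their
population-fraction complement. The sample-embedding analyses use
15 reference batches in two cohorts (cohort shift 0.8, idiosyncratic
batch shift 0.2, 120 cells per batch, 100 features) trained for 300
epochs — embeddings converge more slowly than the network because each row
is informed only by its own sample's cells, and 300 epochs lets the
learned shift dominate the random initialization. The planted correlation
screen uses 60 samples × 30 cells, 1,000 genes with 50 planted effects of
0.4 per unit score on the log scale.

What the generator does **not** emulate: zero inflation beyond NB
sampling, gene–gene correlation within a type, continuous differentiation
trajectories, ambient RNA, doublets, or library-size confounding between
batches. Passing tests therefore demonstrate correctness of the machinery
and recoverability under the stated generative model, not performance on
real atlases.

## Design choices on genuinely open points

- HVG selection is global by default (batch-aware available via
  `per_batch_key`); Seurat-flavor binned dispersion via scanpy with a
  deterministic tie-break and constant features forced to the bottom.
- The unknown-cell quantile is computed over the query population only.
- Covariate association uses OLS with dummy encoding (p = levels − 1);
  ordinal covariates use integer codes (a full ordinal regression is out
  of scope and noted as a divergence).
- Gene–PC correlations and pseudobulks use per-sample means of log1p
  counts; raw p-values with fixed cutoffs (|r| > 0.3, p < 0.01), no FDR
  correction.
- `flag_unknown(q=0)` flags every cell (nothing is trusted), including
  ties at the minimum uncertainty.
- Early stopping is off by default to preserve determinism.

## Known limitations

- The uncertainty is a raw latent distance; its scale varies across
  datasets and thresholds should be inspected per application.
- Louvain modularity over-partitions large homogeneous groups of
  unlabeled cells (a known resolution-limit effect); unlabeled prototypes
  may therefore be finer-grained than the true structure.
- No GPU path and no minibatched sparse input: counts are densified per
  minibatch, which bounds practical size to desk-scale data.
- A single η applies to all annotation levels.
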