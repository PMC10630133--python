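# protomap

Conditional-VAE integration of multi-batch single-cell count data with
**learnable condition embeddings** and **prototype-based cell-type label
transfer**, including frozen-weight query-to-reference mapping and
sample-level embedding analytics.

## The problem

Single-cell atlases are assembled from many samples, studies and assays,
each carrying technical (batch) variation that masks biology. Standard
conditional VAEs absorb batch effects by feeding a one-hot batch indicator
to the encoder and decoder — which scales poorly with hundreds of samples
and treats every batch as unrelated to every other. `protomap` instead
represents each condition level by a trainable vector `s ∈ R^E`:

```
L_CVAE(θ, φ, s) = −E_{z∼q_{φ,s}(z|x,c)} log p_{θ,s}(x|z,c) + D_KL(q_{φ,s}(z|x,c) ‖ N(0,I))
```

with an NB(μ, α) likelihood for RNA counts (Poisson for fragment counts).
The embeddings both reduce parameters — fewer than a one-hot CVAE exactly
when `E < N·H/(N+H)`, `H = H_enc + H_dec` — and form an interpretable
*sample-level* representation: PCA, covariate association (adjusted R²),
kNN sample-phenotype classification and gene–PC correlation screens all
operate on the embedding matrix.

Cell identities are anchored by **prototypes** `p_k`, the mean latent
vector per label. Fine-tuning adds a pull-in term
`η/N · Σ 1[a_i = k] · d(z_i, p_k)` (Minkowski distance, default
Euclidean); label transfer assigns each query cell the label of its
nearest prototype, with the minimizing distance as an uncertainty — cells
above the 90% uncertainty quantile are flagged as potentially novel types.
Mapping a query trains **only** new condition embeddings; encoder, decoder
and reference embeddings stay bitwise frozen, so the reference latent
space never moves.

## Worked example

```python
import numpy as np
import protomap as pm

# synthetic atlas: 5 types, 4 reference + 2 query batches, 200 genes
spec = pm.SyntheticAtlasSpec(seed=1)
reference, query, truth = pm.generate_synthetic_atlas(spec)

model, report = pm.build_reference(reference, pm.ModelConfig(seed=1), n_epochs=100)
mapped, _ = pm.map_query(model, query, n_epochs=100)   # frozen weights

latent = pm.get_latent(query, mapped, mode="mean").mean
protos = pm.PrototypeSet("cell_type", model.prototypes["cell_type"].labeled)
result = pm.flag_unknown(pm.classify(latent, protos), quantile=0.9)

print("accuracy:", (result.predicted == truth).mean())
print("mixing (integrated):", pm.batch_mixing_knn(
    np.vstack([pm.get_latent(reference, mapped).mean, latent]),
    np.concatenate([reference.condition_covariates["sample"],
                    query.condition_covariates["sample"]])))
```

prints

```
accuracy: 1.0
mixing (integrated): 0.897912862590401
```

— every query cell recovers its true type, and the kNN batch-mixing score
of the integrated latent space is 0.90 (1 = perfectly mixed; the log1p-PCA
of the raw counts scores 0.07 on the same cells, i.e. batches are almost
fully separated before integration).

A thin CLI mirrors the library for shell use:

```bash
protomap build-reference ref_dir --format mtx_dir --covariate sample \
    --annotation cell_type --out model.npz
protomap map-query model.npz query_dir --format mtx_dir --covariate sample \
    --out mapped.npz
protomap transfer mapped.npz query_dir --format mtx_dir --out labels.tsv
```

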