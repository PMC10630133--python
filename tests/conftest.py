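import numpy as np
import pytest

import protomap as pm


@pytest.fixture(scope="session")
def small_atlas():
    """Compact multi-batch atlas: 3 types, 3 ref + 1 query batches."""
    spec = pm.SyntheticAtlasSpec(n_cell_types=3, n_batches=4, n_query_batches=1,
                                 cells_per_batch=100, n_features=60, seed=5)
    return pm.generate_synthetic_atlas(spec)


@pytest.fixture(scope="session")
def small_model(small_atlas):
    """Reference model trained briefly on the compact atlas."""
    ref, _, _ = small_atlas
    cfg = pm.ModelConfig(latent_dim=6, embedding_dim=3, seed=5)
    model, report = pm.build_reference(ref, cfg, n_epochs=12)
    return model, report


@pytest.fixture(scope="session")
def atlas_runs():
    """Full-scale synthetic runs (reference + query mapping) for 3 seeds.

    Study conditions: 5 types, 4 reference + 2 query batches, 650 cells per
    batch (~3,900 cells), 200 features, type separation 5x the batch effect.
    """
    runs = {}
    for seed in (1, 2, 3):
        spec = pm.SyntheticAtlasSpec(seed=seed)
        ref, query, truth = pm.generate_synthetic_atlas(spec)
        model, report = pm.build_reference(ref, pm.ModelConfig(seed=seed), n_epochs=100)
        mapped, _ = pm.map_query(model, query, n_epochs=100)
        runs[seed] = {
            "ref": ref, "query": query, "truth": truth,
            "model": model, "mapped": mapped, "report": report,
            "lat_ref": pm.get_latent(ref, mapped, mode="mean").mean,
            "lat_query": pm.get_latent(query, mapped, mode="mean").mean,
        }
    return runs


@pytest.fixture(scope="session")
def heldout_run():
    """Atlas with one type absent from the reference (~10% of query cells)."""
    spec = pm.SyntheticAtlasSpec(n_cell_types=10, held_out_types=frozenset({9}), seed=2)
    ref, query, truth = pm.generate_synthetic_atlas(spec)
    model, _ = pm.build_reference(ref, pm.ModelConfig(seed=2), n_epochs=100)
    mapped, _ = pm.map_query(model, query, n_epochs=100)
    lat = pm.get_latent(query, mapped, mode="mean").mean
    return {"model": model, "mapped": mapped, "truth": truth, "lat_query": lat}


def rand_labels(rng, n, classes):
    return np.asarray(rng.choice(classes, size=n), dtype=object)
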