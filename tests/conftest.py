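import numpy as np
import pandas as pd
import pytest

from noduleseq import simulate
from noduleseq.expression import compute_size_factors


@pytest.fixture(scope="session")
def small_config():
    return simulate.GeneratorConfig(
        n_genes=1500,
        de_fraction=0.03,
        n_duplicate_pairs=80,
        diverged_pair_fraction=0.5,
        n_modules=2,
        module_size=30,
        ncr_count=10,
        decoy_count=20,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """In-memory bundle: counts (post catalog/ct mutation), samples, truth, catalog, pairs."""
    counts, samples, truth = simulate.generate_counts(small_config)
    catalog, pairs = simulate.generate_duplication_catalog(small_config, truth, counts, samples)
    ct = simulate.generate_ct_table(truth, counts, small_config)
    annotation = simulate.generate_annotation(small_config, truth, counts)
    proteins, truth = simulate.generate_proteins(small_config, truth, gene_ids=list(counts.index))
    return {
        "config": small_config,
        "counts": counts,
        "samples": samples,
        "truth": truth,
        "catalog": catalog,
        "pairs": pairs,
        "ct": ct,
        "annotation": annotation,
        "proteins": proteins,
    }


@pytest.fixture(scope="session")
def small_factors(small_bundle):
    return compute_size_factors(small_bundle["counts"])


def two_block_expression(seed, n_blocks=2, block_size=30, n_background=40, n_samples=20, noise_sd=0.1):
    """Expression matrix with latent-factor blocks plus unstructured background."""
    rng = np.random.default_rng(seed)
    rows, labels, latents = [], [], []
    for b in range(n_blocks):
        latent = rng.normal(0.0, 1.0, n_samples)
        latents.append(latent)
        for _ in range(block_size):
            rows.append(8.0 + latent + rng.normal(0.0, noise_sd, n_samples))
            labels.append(b)
    for _ in range(n_background):
        rows.append(8.0 + rng.normal(0.0, 1.0, n_samples))
        labels.append(-1)
    ids = [f"g{i:03d}" for i in range(len(rows))]
    expr = pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=ids), latents
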