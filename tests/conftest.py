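import numpy as np
import pandas as pd
import pytest

from gepatlas import AtlasConfig, generate_atlas


@pytest.fixture(scope="session")
def locked_atlas():
    """Standard study conditions: 40 samples, 12 GEPs in 3 planted hubs,
    within-hub usage correlation 0.7, two GEPs and a gene block shifted in
    inflamed samples."""
    cfg = AtlasConfig(
        n_patients=20,
        samples_per_patient=2,
        cells_per_sample=30,
        n_genes=240,
        compartments=("epithelial", "myeloid"),
        k_true=6,
        within_hub_usage_correlation=0.7,
        inflammation_effect_geps=("pEP01", "pMY02"),
        inflammation_effect_size=1.0,
        signature_genes=tuple(f"G{i:04d}" for i in range(200, 220)),
        seed=1,
    )
    adata, meta, truth = generate_atlas(cfg)
    return cfg, adata, meta, truth


@pytest.fixture(scope="session")
def planted_nmf():
    """Rank-4 planted factorisation with Poisson noise: 2000 cells x 500
    genes, block spectra on a flat floor."""
    rng = np.random.default_rng(0)
    k = 4
    H = np.zeros((k, 500))
    for j in range(k):
        H[j, j * 100 : (j + 1) * 100] = rng.uniform(1, 5, 100)
    H += 0.05
    W0 = rng.gamma(2.0, 1.0, size=(2000, k)) * (rng.random((2000, k)) < 0.6)
    X = rng.poisson(W0 @ H * 2.0).astype(float)
    return X, H, W0


@pytest.fixture(scope="session")
def usage_frame(locked_atlas):
    """Planted usages as a cells x GEPs DataFrame for activity summaries."""
    _, adata, _, truth = locked_atlas
    return pd.DataFrame(truth.W_true, index=adata.obs_names, columns=truth.gep_ids)
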