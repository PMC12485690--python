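"""Shared fixtures: small synthetic inputs generated at test time."""

import numpy as np
import pandas as pd
import pytest

import gliastate as gs


@pytest.fixture(scope="session")
def small_atlas() -> gs.SyntheticAtlas:
    cfg = gs.AtlasConfig(
        n_datasets=2,
        donors_per_group=3,
        n_genes=80,
        cluster_size_nb=(120.0, 3.0),
        proportion_effects={("AD", "Micro_DAM_SPP1"): 1.0},
        seed=11,
    )
    return gs.generate_atlas(cfg)


def simulate_pseudobulk(
    seed: int,
    n_per: int = 10,
    n_genes: int = 600,
    n_de: int = 0,
    lfc: float = 1.0,
    theta: float = 10.0,
    latent_sd: float = 0.0,
    balanced: bool = False,
) -> tuple[gs.PseudobulkMatrix, np.ndarray, np.ndarray]:
    """NB pseudobulk with optional planted log2FC and one latent batch factor.

    With `balanced`, half the planted genes go up and half down, keeping the
    mRNA composition neutral.  Returns (pseudobulk, disease labels, planted
    log2FC vector).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    disease = np.array([0] * n_per + [1] * n_per)
    base = rng.normal(4.0, 1.5, n_genes)
    planted = np.zeros(n_genes)
    planted[:n_de] = lfc
    if balanced:
        planted[n_de // 2 : n_de] = -lfc
    load = rng.normal(0.0, latent_sd, n_genes)
    batch = rng.normal(0.0, 1.0, n)
    mu = 2.0 ** (base[None, :] + planted[None, :] * disease[:, None] + np.outer(batch, load))
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {"disease": disease, "sex": rng.integers(0, 2, n), "age": rng.uniform(60, 90, n)},
        index=cols,
    )
    pb = gs.PseudobulkMatrix(
        counts=pd.DataFrame(counts.T, index=genes, columns=cols), sample_meta=meta
    )
    return pb, disease, planted
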