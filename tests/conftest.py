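import numpy as np
import pandas as pd
import pytest

from seedomics import SimConfig, StageDesign, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    return generate_dataset(
        SimConfig(
            n_genes=300,
            n_metabolites=6,
            n_clusters_planted=6,
            n_modules_planted=2,
            module_size=20,
            noise_sd=0.2,
            n_decoy_members=3,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def expr_design():
    return StageDesign.balanced(3)


@pytest.fixture(scope="session")
def metab_design():
    return StageDesign.balanced(6)


def exact_correlation_data(
    corr: np.ndarray, n_samples: int, seed: int = 0, prefix: str = "g"
) -> pd.DataFrame:
    """genes x samples matrix whose *sample* correlation matrix equals ``corr``.

    Centered orthonormal sample-space directions are mixed through the
    Cholesky factor of the target matrix, so planted correlations hold
    exactly, not just in expectation. Requires n_samples > n_genes.
    """
    rng = np.random.default_rng(seed)
    p = corr.shape[0]
    g = rng.standard_normal((n_samples, p + 1))
    g -= g.mean(axis=0)
    q, _ = np.linalg.qr(g)
    q = q[:, :p]
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(p))
    return pd.DataFrame(
        (q @ chol.T).T, index=[f"{prefix}{i}" for i in range(p)]
    )


def two_block_correlation(block: int = 8, within: float = 0.9) -> np.ndarray:
    p = 2 * block
    corr = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                corr[i, j] = 1.0
            elif (i < block) == (j < block):
                corr[i, j] = within
    return corr
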