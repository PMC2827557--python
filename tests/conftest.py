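import numpy as np
import pandas as pd
import pytest

from dcsig import INFLAMMATORY, NON_INFLAMMATORY, SyntheticConfig, generate_expression


def make_two_class_matrix(
    n_genes: int, n_planted: int, n_per_class: int, effect: float, seed: int
) -> tuple[pd.DataFrame, dict[str, str], list[str]]:
    """Gaussian matrix with the first ``n_planted`` genes shifted up in the
    inflammatory class; returns (matrix, labels, planted gene ids)."""
    rng = np.random.default_rng(seed)
    genes = [f"{100000 + i}_at" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(2 * n_per_class)]
    labels = {
        s: (INFLAMMATORY if i < n_per_class else NON_INFLAMMATORY)
        for i, s in enumerate(samples)
    }
    X = rng.normal(0.0, 1.0, size=(n_genes, 2 * n_per_class))
    X[:n_planted, :n_per_class] += effect
    return pd.DataFrame(X, index=genes, columns=samples), labels, genes[:n_planted]


def make_separable_matrix(n_per_class: int = 20, seed: int = 0):
    """One gene with disjoint class ranges plus noise genes."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i:03d}" for i in range(2 * n_per_class)]
    labels = {
        s: (INFLAMMATORY if i < n_per_class else NON_INFLAMMATORY)
        for i, s in enumerate(samples)
    }
    sep = np.concatenate(
        [rng.uniform(5.0, 6.0, n_per_class), rng.uniform(8.0, 9.0, n_per_class)]
    )
    noise = rng.normal(0.0, 1.0, size=(3, 2 * n_per_class))
    m = pd.DataFrame(
        np.vstack([sep, noise]),
        index=["sep_at", "n1_at", "n2_at", "n3_at"],
        columns=samples,
    )
    return m, labels


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study preset (small gene count for speed)."""
    cfg = SyntheticConfig(n_genes=400, seed=11)
    matrix, sheet, qc, truth = generate_expression(cfg)
    return cfg, matrix, sheet, qc, truth


@pytest.fixture(scope="session")
def separable():
    return make_separable_matrix()
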