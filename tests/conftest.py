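import numpy as np
import pandas as pd
import pytest

from bara import Dataset, EvaluationConfig, as_expression_matrix


@pytest.fixture
def toy_train():
    """4x2 worked example: gene means (2, 0), singular values (sqrt8, sqrt2)."""
    return as_expression_matrix(
        [[1.0, 0.0], [3.0, 0.0], [2.0, 2.0], [2.0, -2.0]],
        sample_ids=["s0", "s1", "s2", "s3"],
    )


def make_separable_dataset(name, n_per_group=12, n_genes=20, gap=10.0, noise=0.1, seed=0):
    """Two well-separated clusters at 0 and `gap` on every gene."""
    rng = np.random.default_rng(seed)
    centers = np.repeat([[0.0], [gap]], n_per_group, axis=0)
    values = centers + rng.normal(0, noise, size=(2 * n_per_group, n_genes))
    ids = [f"{name}_s{i}" for i in range(2 * n_per_group)]
    matrix = pd.DataFrame(values, index=ids, columns=[f"g{j}" for j in range(n_genes)])
    ann = pd.DataFrame(
        {"group": ["A"] * n_per_group + ["B"] * n_per_group}, index=ids
    )
    return Dataset(name=name, matrix=matrix, annotations=ann)


@pytest.fixture
def separable_pair():
    return make_separable_dataset("train", seed=0), make_separable_dataset("test", seed=1)


@pytest.fixture
def fast_config():
    """Small protocol settings for unit tests (one-point kNN grid)."""
    return EvaluationConfig(
        n_top_genes=10,
        n_references=3,
        n_iterations=3,
        cv_repeats=1,
        cv_folds=4,
        classifier="knn",
        classifier_grid=[{"n_neighbors": 3}],
        normalizer="none",
        rng_seed=5,
    )
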