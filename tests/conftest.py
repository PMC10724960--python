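import numpy as np
import pytest

from cssmo import (
    CSSMOConfig,
    ExpressionDataset,
    SyntheticSpec,
    discretize_expression,
    generate_synthetic_dataset,
    make_knn_fitness,
    mrmr_select,
    normalize_expression,
)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 samples x 3 genes, two classes, fully hand-checkable."""
    return ExpressionDataset(
        matrix=np.array(
            [[0.0, 5.0, 1.0], [0.1, 5.0, 2.0], [1.0, 5.0, 3.0], [1.1, 5.0, 4.0]]
        ),
        labels=np.array([0, 0, 1, 1]),
        gene_ids=("gA", "gB", "gC"),
        sample_ids=("s1", "s2", "s3", "s4"),
        class_names=("neg", "pos"),
    )


@pytest.fixture(scope="session")
def recovery_benchmark():
    """The bundled planted-signal benchmark: 60 samples x 500 genes,
    5 informative genes at effect 2.0 with 4 redundant copies each,
    minmax-normalized, mRMR pool of 50."""
    dataset, truth = generate_synthetic_dataset(SyntheticSpec(seed=0))
    dataset = normalize_expression(dataset, "minmax_per_gene")
    disc = discretize_expression(dataset)
    pool = mrmr_select(disc, dataset.labels, k=50)
    fitness_fn = make_knn_fitness(dataset, pool, k=1)
    return dataset, truth, pool, fitness_fn


@pytest.fixture
def small_config() -> CSSMOConfig:
    """Reduced optimizer configuration used for fast seeded runs."""
    return CSSMOConfig(swarm_size=20, n_nests=20, n_generations=30, seed=0)
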