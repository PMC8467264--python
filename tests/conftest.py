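import numpy as np
import pytest

from singnet import ExpressionMatrix, GeneSetCollection


def random_instance(rng, n_genes=None, n_sets=None, n_samples=5):
    """Small random expression + gene-set instance for oracle comparisons."""
    n_genes = n_genes if n_genes is not None else int(rng.integers(6, 21))
    n_sets = n_sets if n_sets is not None else int(rng.integers(3, 9))
    gene_ids = tuple(f"g{i}" for i in range(n_genes))
    sample_ids = tuple(f"s{j}" for j in range(n_samples))
    values = rng.lognormal(1.0, 1.0, size=(n_genes, n_samples))
    members = {}
    set_names = []
    for q in range(n_sets):
        size = int(rng.integers(2, max(3, n_genes // 2 + 1)))
        picks = rng.choice(n_genes, size=size, replace=False)
        name = f"SET{q}"
        set_names.append(name)
        members[name] = tuple(gene_ids[i] for i in sorted(picks))
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    sets = GeneSetCollection(set_names=tuple(set_names), members=members)
    return expr, sets


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_expr():
    """3 genes x 2 samples with easily hand-checked values."""
    return ExpressionMatrix(
        gene_ids=("g1", "g2", "g3"),
        sample_ids=("s1", "s2"),
        values=np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]]),
    )


@pytest.fixture
def tiny_sets():
    return GeneSetCollection(
        set_names=("A", "B"),
        members={"A": ("g1", "g2"), "B": ("g2", "g3")},
    )
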