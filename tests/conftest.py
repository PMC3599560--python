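import numpy as np
import pytest

from relexp.datamodel import CLASS_1, CLASS_2, ExpressionDataset


def make_dataset(values, class1_count=None, gene_ids=None, sample_ids=None, labels=None):
    """Build an ExpressionDataset from a 2-D array.

    If ``class1_count`` is given, the first ``class1_count`` samples are
    class 1 and the rest class 2.
    """
    values = np.asarray(values, dtype=float)
    g, m = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids = sample_ids or [f"s{j}" for j in range(m)]
    if labels is None and class1_count is not None:
        labels = {s: (CLASS_1 if j < class1_count else CLASS_2) for j, s in enumerate(sample_ids)}
    return ExpressionDataset(gene_ids, sample_ids, values, labels)


def random_dataset(seed, n_genes, n1, n2):
    """Continuous random two-class dataset (no planted signal, no ties)."""
    rng = np.random.default_rng(seed)
    return make_dataset(rng.normal(size=(n_genes, n1 + n2)), class1_count=n1)


def cyclic_triple_dataset(extra_genes=0, seed=0):
    """3 + 3 samples enumerating the cyclic / anti-cyclic orderings.

    Class 1 realises each of the three cyclic orderings of (g0, g1, g2)
    exactly once; class 2 the three anti-cyclic ones.  The induced pair
    probabilities are exactly 2/3 vs 1/3, so every pairwise Delta is
    1/3 while the triple's ordering distributions have disjoint support
    (TV score 1).
    """
    # column = values of (g0, g1, g2); class 1: cyclic ascending orders
    cols_c1 = [(1.0, 2.0, 3.0), (3.0, 1.0, 2.0), (2.0, 3.0, 1.0)]
    # class 2: anti-cyclic ascending orders
    cols_c2 = [(1.0, 3.0, 2.0), (2.0, 1.0, 3.0), (3.0, 2.0, 1.0)]
    values = np.array(cols_c1 + cols_c2, dtype=float).T
    if extra_genes:
        rng = np.random.default_rng(seed)
        noise = rng.normal(loc=10.0, size=(extra_genes, 6))
        values = np.vstack([values, noise])
    return make_dataset(values, class1_count=3)


@pytest.fixture
def planted_pair_dataset():
    """One perfect pair reversal among noise genes, 15 + 15 samples."""
    from relexp.synthetic import PairReversal, SyntheticSpec, generate

    spec = SyntheticSpec(
        n_genes=20,
        n_samples_per_class=15,
        noise_sd=1.0,
        planted=(PairReversal(3, 7, gap=8.0),),
        seed=11,
    )
    ds, _ = generate(spec)
    return ds
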