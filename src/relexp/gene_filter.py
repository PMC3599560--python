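"""Rank-based differential-expression pre-filter.

TSP, k-TSP and TST search over gene pairs or triples, so their cost
grows polynomially in the number of genes; restricting the search to
the top-n most differential genes is the standard cost (and
over-fitting) control.  Each gene is scored with the centred two-sample
Wilcoxon rank-sum (Mann-Whitney) statistic ``|U - n1*n2/2|``, where
``U`` counts (class-1, class-2) sample pairs in which the class-1 value
is larger, ties counting 0.5.  Only the gene *ranking* matters for
top-n selection, so no p-value or normal approximation is involved, and
the score is invariant under monotone transforms of a gene's values.

The filter must be refit on the training samples of every
cross-validation fold; selecting genes on the full dataset before CV
would leak the test labels into the signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datamodel import CLASS_1, CLASS_2, DataError, ExpressionDataset


@dataclass
class GeneScore:
    """Per-gene separation score; larger = more differential."""

    gene_id: str
    statistic: float


def _u_statistics(dataset: ExpressionDataset) -> np.ndarray:
    """Mann-Whitney U (class 1 over class 2, ties 0.5) for every gene."""
    dataset.require_two_classes()
    x1 = dataset.class_matrix(CLASS_1)
    x2 = dataset.class_matrix(CLASS_2)
    n1 = x1.shape[1]
    combined = np.concatenate([x1, x2], axis=1)
    ranks = rankdata(combined, method="average", axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    # U = R1 - n1(n1+1)/2 under the average-rank convention == pairwise
    # count of class-1 > class-2 with ties contributing 0.5.
    return r1 - n1 * (n1 + 1) / 2.0


def rank_sum_score(dataset: ExpressionDataset, gene_id: str) -> GeneScore:
    """Centred rank-sum statistic ``|U - n1*n2/2|`` for one gene."""
    idx = dataset.gene_index(gene_id)
    n1, n2 = dataset.class_sizes()
    u = _u_statistics(dataset)[idx]
    return GeneScore(gene_id, float(abs(u - n1 * n2 / 2.0)))


def score_all_genes(dataset: ExpressionDataset) -> np.ndarray:
    """Centred rank-sum statistic for every gene, in dataset order."""
    n1, n2 = dataset.class_sizes()
    u = _u_statistics(dataset)
    return np.abs(u - n1 * n2 / 2.0)


def select_top_genes(dataset: ExpressionDataset, n: int) -> ExpressionDataset:
    """Restrict to the n most differential genes (training samples only).

    Ties on the statistic are broken by original gene order, and the
    selected genes keep their dataset order, so ``n == n_genes`` is the
    identity.
    """
    if not 1 <= n <= dataset.n_genes:
        raise DataError(f"n must be in [1, {dataset.n_genes}], got {n}")
    if n == dataset.n_genes:
        return dataset
    stats = score_all_genes(dataset)
    # stable sort on descending score keeps earlier genes first on ties
    order = np.argsort(-stats, kind="stable")[:n]
    keep = np.sort(order)  # preserve dataset gene order among the selected
    return dataset.subset_genes([dataset.gene_ids[i] for i in keep])
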