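"""Top-Scoring Pair (TSP) classifier.

TSP searches for the gene pair (i, j) whose ordering is most consistent
within each class and most different between classes.  With

    p_c = P(X_i < X_j | class c)

estimated as the empirical within-class frequency (a sample with
X_i == X_j contributes 0.5), the pair score is Delta = |p_1 - p_2|; the
trained classifier is the single pair maximising Delta over all pairs
of the (optionally rank-sum-filtered) gene set.

Ties on Delta are broken by a secondary rank score
Gamma = |(r1_i - r2_i) - (r1_j - r2_j)|, where ``rc_g`` is the mean
within-sample rank of gene g in class c — the pair whose rank gap moves
most between classes — and remaining ties lexicographically by gene
position, so training is fully deterministic and identical to
exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .datamodel import (
    CLASS_1,
    CLASS_2,
    DataError,
    ExpressionDataset,
    Learner,
    rank_matrix,
)
from .gene_filter import select_top_genes


@dataclass
class PairScore:
    """Score of one gene pair (gene_i before gene_j in dataset order)."""

    gene_i: str
    gene_j: str
    p1: float  # P(X_i < X_j | class 1)
    p2: float  # P(X_i < X_j | class 2)
    delta: float  # |p1 - p2|
    gamma: float  # secondary rank-gap score


@dataclass
class TSPClassifier:
    pair: PairScore
    class_priors: tuple[int, int]  # training sample counts (class 1, class 2)

    @property
    def orientation(self) -> int:
        """Class predicted when X_i < X_j is observed (ties toward class 1)."""
        return CLASS_1 if self.pair.p1 >= self.pair.p2 else CLASS_2

    def to_dict(self) -> dict:
        return {
            "algorithm": "tsp",
            "gene_i": self.pair.gene_i,
            "gene_j": self.pair.gene_j,
            "p1": self.pair.p1,
            "p2": self.pair.p2,
            "delta": self.pair.delta,
            "gamma": self.pair.gamma,
            "orientation": self.orientation,
            "class_priors": list(self.class_priors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TSPClassifier":
        pair = PairScore(d["gene_i"], d["gene_j"], d["p1"], d["p2"], d["delta"], d["gamma"])
        return cls(pair, tuple(d["class_priors"]))


def order_probability(
    dataset: ExpressionDataset, class_label: int, gene_i: str, gene_j: str
) -> float:
    """Empirical P(X_i < X_j | class); a tied sample contributes 0.5."""
    x = dataset.class_matrix(class_label)
    if x.shape[1] == 0:
        raise DataError(f"class {class_label} has no samples")
    vi = x[dataset.gene_index(gene_i)]
    vj = x[dataset.gene_index(gene_j)]
    return float(((vi < vj).sum() + 0.5 * (vi == vj).sum()) / x.shape[1])


def pair_score(dataset: ExpressionDataset, gene_i: str, gene_j: str) -> PairScore:
    """Delta and Gamma for one pair (oriented so gene_i precedes gene_j)."""
    if gene_i == gene_j:
        raise DataError("a pair needs two distinct genes")
    dataset.require_two_classes()
    p1 = order_probability(dataset, CLASS_1, gene_i, gene_j)
    p2 = order_probability(dataset, CLASS_2, gene_i, gene_j)
    gaps = _rank_gaps(dataset)
    i, j = dataset.gene_index(gene_i), dataset.gene_index(gene_j)
    return PairScore(gene_i, gene_j, p1, p2, abs(p1 - p2), float(abs(gaps[i] - gaps[j])))


def _rank_gaps(dataset: ExpressionDataset) -> np.ndarray:
    """Per gene: mean within-sample rank in class 1 minus in class 2."""
    ranks = rank_matrix(dataset)
    idx1 = [dataset.sample_index(s) for s in dataset.class_sample_ids(CLASS_1)]
    idx2 = [dataset.sample_index(s) for s in dataset.class_sample_ids(CLASS_2)]
    return ranks[:, idx1].mean(axis=1) - ranks[:, idx2].mean(axis=1)


def _order_probability_matrix(x: np.ndarray) -> np.ndarray:
    """P[i, j] = empirical P(X_i < X_j) over the columns of x."""
    m = x.shape[1]
    less = (x[:, None, :] < x[None, :, :]).sum(axis=2)
    eq = (x[:, None, :] == x[None, :, :]).sum(axis=2)
    return (less + 0.5 * eq) / m


def score_all_pairs(dataset: ExpressionDataset):
    """Delta/Gamma matrices plus the upper-triangle index arrays.

    Returns ``(iu, ju, delta, gamma)`` where ``delta``/``gamma`` are
    G x G matrices and ``iu``/``ju`` index the strict upper triangle.
    """
    dataset.require_two_classes()
    p1 = _order_probability_matrix(dataset.class_matrix(CLASS_1))
    p2 = _order_probability_matrix(dataset.class_matrix(CLASS_2))
    delta = np.abs(p1 - p2)
    gaps = _rank_gaps(dataset)
    gamma = np.abs(gaps[:, None] - gaps[None, :])
    iu, ju = np.triu_indices(dataset.n_genes, k=1)
    return iu, ju, delta, gamma, p1, p2


def _best_pair_index(iu, ju, delta, gamma) -> int:
    """Index into (iu, ju) of the winner under (delta, gamma, lex) order."""
    d = delta[iu, ju]
    g = gamma[iu, ju]
    # lexsort: last key is primary; iu/ju ascending break remaining ties
    order = np.lexsort((ju, iu, -g, -d))
    return int(order[0])


def train_tsp(
    dataset: ExpressionDataset, params: Mapping | None = None
) -> TSPClassifier:
    """Exhaustively find the maximal-Delta pair on the filtered gene set.

    ``params['filter_n']`` (optional) restricts the search to the top-n
    rank-sum genes; the result is identical to brute-force enumeration
    over all remaining pairs.
    """
    params = dict(params or {})
    filter_n = params.get("filter_n")
    dataset.require_two_classes()
    if filter_n:
        dataset = select_top_genes(dataset, min(int(filter_n), dataset.n_genes))
    if dataset.n_genes < 2:
        raise DataError("TSP needs at least two genes after filtering")
    iu, ju, delta, gamma, p1, p2 = score_all_pairs(dataset)
    b = _best_pair_index(iu, ju, delta, gamma)
    i, j = int(iu[b]), int(ju[b])
    pair = PairScore(
        dataset.gene_ids[i],
        dataset.gene_ids[j],
        float(p1[i, j]),
        float(p2[i, j]),
        float(delta[i, j]),
        float(gamma[i, j]),
    )
    return TSPClassifier(pair, dataset.class_sizes())


def classify_tsp(classifier: TSPClassifier, sample_vector: Mapping[str, float]) -> int:
    """Predict from the ordering of the trained pair in one sample."""
    pair = classifier.pair
    try:
        xi = sample_vector[pair.gene_i]
        xj = sample_vector[pair.gene_j]
    except KeyError as e:
        raise KeyError(f"sample vector missing gene {e.args[0]!r}") from None
    n1, n2 = classifier.class_priors
    majority = CLASS_1 if n1 >= n2 else CLASS_2
    if xi == xj or pair.p1 == pair.p2:
        return majority
    low_class = CLASS_1 if pair.p1 > pair.p2 else CLASS_2
    if xi < xj:
        return low_class
    return CLASS_2 if low_class == CLASS_1 else CLASS_1


class TSPLearner(Learner):
    """Learner-contract wrapper around :func:`train_tsp`/:func:`classify_tsp`."""

    name = "tsp"

    def train(self, dataset, params=None):
        return train_tsp(dataset, params)

    def classify(self, model, sample_vector):
        return classify_tsp(model, sample_vector)
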