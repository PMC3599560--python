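"""Top-Scoring Triplet (TST) classifier.

A gene triple (i, j, k) induces, within each sample, one of the six
possible orderings of its three expression values.  Each class
therefore has an empirical distribution over the six permutations, and
the TST score of a triple is the total-variation distance between the
two class distributions,

    score = (1/2) * sum over the 6 permutations |p1(pi) - p2(pi)|,

which lies in [0, 1], reduces to TSP's |p1 - p2| when projected onto a
pair, and hits 1 exactly when the class supports are disjoint.  A
sample with tied values splits its mass equally over the compatible
permutations.  Training is an exhaustive search over all C(G, 3)
triples of the (rank-sum-filtered) gene set — the filter is the cost
control that makes the cubic search feasible.

Classification computes the new sample's permutation (ties resolved by
average-rank ordering with gene-order tie-break) and predicts the class
whose training distribution gives it more mass, falling back to the
majority training class when both classes give it equal (possibly zero)
probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    CLASS_1,
    CLASS_2,
    DataError,
    ExpressionDataset,
    Learner,
)
from .gene_filter import select_top_genes

#: The six orderings, each written as the gene slots in ascending value
#: order: (0, 1, 2) means X_i < X_j < X_k.
PERMS: tuple[tuple[int, int, int], ...] = tuple(permutations(range(3)))

# comparison code 4*(xi<xj) + 2*(xi<xk) + (xj<xk) -> index into PERMS
_CODE_TO_PERM = {7: 0, 6: 1, 3: 2, 1: 3, 4: 4, 0: 5}

DEFAULT_TST_FILTER_N = 200  # cubic search: cap the gene set by default


@dataclass
class TSTClassifier:
    triple: tuple[str, str, str]
    dist1: np.ndarray  # class-1 frequencies over PERMS
    dist2: np.ndarray
    score: float  # total-variation distance
    class_priors: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "algorithm": "tst",
            "triple": list(self.triple),
            "dist1": [float(x) for x in self.dist1],
            "dist2": [float(x) for x in self.dist2],
            "score": self.score,
            "class_priors": list(self.class_priors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TSTClassifier":
        return cls(
            tuple(d["triple"]),
            np.array(d["dist1"]),
            np.array(d["dist2"]),
            d["score"],
            tuple(d["class_priors"]),
        )


def _compatible_perms(x: Sequence[float]) -> list[int]:
    """Indices of PERMS consistent with the (weak) ordering of x."""
    return [
        t
        for t, p in enumerate(PERMS)
        if x[p[0]] <= x[p[1]] <= x[p[2]]
    ]


def ordering_distribution(
    dataset: ExpressionDataset, class_label: int, triple: Sequence[str]
) -> np.ndarray:
    """Empirical frequencies of the 6 orderings of a triple in one class.

    A sample with tied values contributes equal fractions to every
    compatible permutation, so the six frequencies always sum to 1.
    """
    if len(set(triple)) != 3:
        raise DataError("a triple needs three distinct genes")
    x = dataset.class_matrix(class_label)
    if x.shape[1] == 0:
        raise DataError(f"class {class_label} has no samples")
    rows = [x[dataset.gene_index(g)] for g in triple]
    freqs = np.zeros(6)
    for s in range(x.shape[1]):
        vals = (rows[0][s], rows[1][s], rows[2][s])
        compat = _compatible_perms(vals)
        for t in compat:
            freqs[t] += 1.0 / len(compat)
    return freqs / x.shape[1]


def tst_score(dist1: np.ndarray, dist2: np.ndarray) -> float:
    """Total-variation distance between two ordering distributions."""
    tv = float(0.5 * np.abs(np.asarray(dist1) - np.asarray(dist2)).sum())
    return min(max(tv, 0.0), 1.0)  # guard float round-off at the extremes


def _class_counts(x: np.ndarray, tri_i, tri_j, tri_k) -> np.ndarray:
    """Permutation counts per triple for one class; shape (T, 6).

    Vectorised over the tie-free samples; (sample, triple) entries with
    ties are redistributed per-entry, equal mass to each compatible
    permutation.
    """
    n_triples = len(tri_i)
    counts = np.zeros((n_triples, 6))
    m = x.shape[1]
    if m == 0:
        raise DataError("class has no samples")
    less = x[:, None, :] < x[None, :, :]
    eq = x[:, None, :] == x[None, :, :]
    codes = (
        4 * less[tri_i, tri_j].astype(np.int8)
        + 2 * less[tri_i, tri_k].astype(np.int8)
        + less[tri_j, tri_k].astype(np.int8)
    )  # (T, m)
    tied = eq[tri_i, tri_j] | eq[tri_i, tri_k] | eq[tri_j, tri_k]
    for code, perm_idx in _CODE_TO_PERM.items():
        counts[:, perm_idx] = ((codes == code) & ~tied).sum(axis=1)
    for t, s in zip(*np.nonzero(tied)):
        vals = (x[tri_i[t], s], x[tri_j[t], s], x[tri_k[t], s])
        compat = _compatible_perms(vals)
        for p in compat:
            counts[t, p] += 1.0 / len(compat)
    return counts


def train_tst(dataset: ExpressionDataset, params: Mapping | None = None) -> TSTClassifier:
    """Exhaustive maximisation of the TV score over all gene triples.

    ``params['filter_n']`` restricts the search to the top-n rank-sum
    genes (default cap 200).  Ties on the score are broken by
    lexicographic triple order, so the result equals brute-force
    enumeration.
    """
    params = dict(params or {})
    dataset.require_two_classes()
    filter_n = params.get("filter_n", DEFAULT_TST_FILTER_N)
    if filter_n:
        dataset = select_top_genes(dataset, min(int(filter_n), dataset.n_genes))
    g = dataset.n_genes
    if g < 3:
        raise DataError("TST needs at least three genes after filtering")
    tri = np.array(list(combinations(range(g), 3)))  # lexicographic order
    tri_i, tri_j, tri_k = tri[:, 0], tri[:, 1], tri[:, 2]
    x1 = dataset.class_matrix(CLASS_1)
    x2 = dataset.class_matrix(CLASS_2)
    m1, m2 = x1.shape[1], x2.shape[1]
    c1 = _class_counts(x1, tri_i, tri_j, tri_k)
    c2 = _class_counts(x2, tri_i, tri_j, tri_k)
    # per-sample tie splits are multiples of 1/6, so 6*counts are integers;
    # score the triples in exact integer arithmetic to keep ties exact
    n1 = np.rint(6.0 * m2 * c1).astype(np.int64)
    n2 = np.rint(6.0 * m1 * c2).astype(np.int64)
    tv = np.abs(n1 - n2).sum(axis=1) / (12.0 * m1 * m2)
    p1 = c1 / m1
    p2 = c2 / m2
    best = int(np.argmax(tv))  # first max = lexicographically first triple
    triple = (
        dataset.gene_ids[tri_i[best]],
        dataset.gene_ids[tri_j[best]],
        dataset.gene_ids[tri_k[best]],
    )
    return TSTClassifier(triple, p1[best], p2[best], float(tv[best]), dataset.class_sizes())


def sample_permutation(values: Sequence[float]) -> int:
    """PERMS index of a sample's ordering; ties broken by gene order."""
    order = tuple(int(i) for i in np.argsort(values, kind="stable"))
    return PERMS.index(order)


def classify_tst(classifier: TSTClassifier, sample_vector: Mapping[str, float]) -> int:
    """Predict the class giving the observed permutation more mass."""
    try:
        vals = [sample_vector[g] for g in classifier.triple]
    except KeyError as e:
        raise KeyError(f"sample vector missing gene {e.args[0]!r}") from None
    t = sample_permutation(vals)
    q1, q2 = classifier.dist1[t], classifier.dist2[t]
    if q1 > q2:
        return CLASS_1
    if q2 > q1:
        return CLASS_2
    n1, n2 = classifier.class_priors
    return CLASS_1 if n1 >= n2 else CLASS_2


class TSTLearner(Learner):
    """Learner-contract wrapper around TST training and classification."""

    name = "tst"

    def train(self, dataset, params=None):
        return train_tst(dataset, params)

    def classify(self, model, sample_vector):
        return classify_tst(model, sample_vector)
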