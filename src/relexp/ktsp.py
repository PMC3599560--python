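"""k-Top-Scoring-Pairs (k-TSP) classifier.

k-TSP combines the k best gene-disjoint pairs (each gene may appear in
only one pair) by majority vote.  Pairs are ranked by the TSP order
(Delta desc, Gamma desc, lexicographic) and selected greedily from the
top of the ranking, skipping any pair that reuses a gene.  k is
restricted to odd values so the vote can never tie, and is chosen by
stratified internal cross-validation — the candidate odd k in
{1, 3, ..., k_max} with the highest inner MCC wins, smallest k on ties.
Gene filtering and pair ranking are refit inside every inner fold to
keep the selection honest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .datamodel import (
    CLASS_1,
    CLASS_2,
    DataError,
    ExpressionDataset,
    Learner,
)
from .gene_filter import select_top_genes
from .tsp import PairScore, TSPClassifier, classify_tsp, score_all_pairs

logger = logging.getLogger(__name__)

DEFAULT_K_MAX = 10
DEFAULT_INNER_FOLDS = 5


@dataclass
class KTSPClassifier:
    pairs: list[TSPClassifier]  # in rank order; gene-disjoint; odd count
    k: int
    class_priors: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "algorithm": "ktsp",
            "k": self.k,
            "pairs": [p.to_dict() for p in self.pairs],
            "class_priors": list(self.class_priors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KTSPClassifier":
        return cls(
            [TSPClassifier.from_dict(p) for p in d["pairs"]],
            d["k"],
            tuple(d["class_priors"]),
        )


def rank_all_pairs(dataset: ExpressionDataset) -> list[PairScore]:
    """All gene pairs sorted by (Delta desc, Gamma desc, lexicographic)."""
    if dataset.n_genes < 2:
        raise DataError("pair ranking needs at least two genes")
    import numpy as np

    iu, ju, delta, gamma, p1, p2 = score_all_pairs(dataset)
    d = delta[iu, ju]
    g = gamma[iu, ju]
    order = np.lexsort((ju, iu, -g, -d))
    genes = dataset.gene_ids
    return [
        PairScore(
            genes[iu[t]],
            genes[ju[t]],
            float(p1[iu[t], ju[t]]),
            float(p2[iu[t], ju[t]]),
            float(d[t]),
            float(g[t]),
        )
        for t in order
    ]


def select_disjoint_pairs(ranked_pairs: Sequence[PairScore], k_max: int) -> list[PairScore]:
    """Greedy scan accepting a pair iff neither gene is already used."""
    if k_max < 1:
        raise DataError("k_max must be >= 1")
    used: set[str] = set()
    chosen: list[PairScore] = []
    for p in ranked_pairs:
        if p.gene_i in used or p.gene_j in used:
            continue
        chosen.append(p)
        used.update((p.gene_i, p.gene_j))
        if len(chosen) == k_max:
            break
    return chosen


def _odd_trim(pairs: Sequence, k: int) -> list:
    """First min(k, available) pairs, trimmed to an odd count (>=1)."""
    sub = list(pairs[: min(k, len(pairs))])
    if len(sub) % 2 == 0 and len(sub) > 1:
        sub = sub[:-1]
    return sub


def _vote(pairs: Sequence[TSPClassifier], sample_vector, class_priors) -> int:
    votes1 = sum(1 for p in pairs if classify_tsp(p, sample_vector) == CLASS_1)
    votes2 = len(pairs) - votes1
    if votes1 > votes2:
        return CLASS_1
    if votes2 > votes1:
        return CLASS_2
    n1, n2 = class_priors
    return CLASS_1 if n1 >= n2 else CLASS_2


def _build_pairs(dataset: ExpressionDataset, k: int, filter_n) -> list[TSPClassifier]:
    if filter_n:
        dataset = select_top_genes(dataset, min(int(filter_n), dataset.n_genes))
    ranked = rank_all_pairs(dataset)
    chosen = _odd_trim(select_disjoint_pairs(ranked, k), k)
    priors = dataset.class_sizes()
    return [TSPClassifier(p, priors) for p in chosen]


def choose_k(
    dataset: ExpressionDataset,
    k_max: int = DEFAULT_K_MAX,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
    filter_n: int | None = None,
) -> int:
    """Pick the odd k <= k_max with the best stratified inner-CV MCC.

    The inner confusion matrix is pooled over folds into one MCC per
    candidate; ties go to the smallest k.  If a class has fewer samples
    than ``inner_folds`` the fold count is lowered (and logged).
    """
    from .evaluation import mcc, stratified_folds, ConfusionMatrix

    if k_max < 1:
        raise DataError("k_max must be >= 1")
    candidates = list(range(1, k_max + 1, 2))
    if len(candidates) == 1:
        return 1
    dataset.require_two_classes()
    folds = stratified_folds(dataset, inner_folds, seed)
    pooled = {k: ConfusionMatrix() for k in candidates}
    labeled = dataset.labeled_sample_ids()
    for fold in folds:
        train_ids = [s for s in labeled if s not in set(fold)]
        train_ds = dataset.subset_samples(train_ids)
        pairs = _build_pairs(train_ds, max(candidates), filter_n)
        priors = train_ds.class_sizes()
        for k in candidates:
            sub = _odd_trim(pairs, k)
            for sid in fold:
                pred = _vote(sub, dataset.sample_vector(sid), priors)
                pooled[k].add(dataset.class_of[sid], pred)
    best_k, best_mcc = None, None
    for k in candidates:  # ascending: smallest k wins ties
        m = mcc(pooled[k])
        if best_mcc is None or m > best_mcc:
            best_k, best_mcc = k, m
    return best_k


def train_ktsp(dataset: ExpressionDataset, params: Mapping | None = None) -> KTSPClassifier:
    """Choose k by inner CV, then build the final disjoint pair list.

    Recognised params: ``filter_n``, ``k_max`` (default 10),
    ``inner_folds`` (default 5), ``seed`` (default 0).
    """
    params = dict(params or {})
    dataset.require_two_classes()
    k_max = int(params.get("k_max", DEFAULT_K_MAX))
    inner_folds = int(params.get("inner_folds", DEFAULT_INNER_FOLDS))
    seed = int(params.get("seed", 0))
    filter_n = params.get("filter_n")
    k = choose_k(dataset, k_max, inner_folds, seed, filter_n)
    pairs = _build_pairs(dataset, k, filter_n)
    if not pairs:
        raise DataError("no pairs available for k-TSP")
    if len(pairs) < k:
        logger.info("only %d disjoint pairs available (k=%d requested)", len(pairs), k)
    return KTSPClassifier(pairs, len(pairs), dataset.class_sizes())


def classify_ktsp(classifier: KTSPClassifier, sample_vector: Mapping[str, float]) -> int:
    """Majority vote of the k pairs (odd k: the vote cannot tie)."""
    return _vote(classifier.pairs, sample_vector, classifier.class_priors)


class KTSPLearner(Learner):
    """Learner-contract wrapper around k-TSP training and voting."""

    name = "ktsp"

    def train(self, dataset, params=None):
        return train_ktsp(dataset, params)

    def classify(self, model, sample_vector):
        return classify_ktsp(model, sample_vector)
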