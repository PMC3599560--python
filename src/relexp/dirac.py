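"""Differential Rank Conservation (DIRAC) classifier.

DIRAC works at the level of predefined gene sets ("networks", e.g.
pathways from a GMT file).  For each network and class it learns a
*rank template*: one bit per gene pair (i, j) recording whether gene i
exceeds gene j in the majority of that class's samples.  A sample's
*rank matching score* against a template is the fraction of network
pairs whose ordering in the sample agrees with the template bit (a tied
pair matches neither orientation).  Averaging each class's samples
against their own template gives the *rank conservation index* — how
tightly the network's ordering is conserved within the class.

For classification, a network's two templates act as a nearest-template
rule: a sample is assigned to the class whose template it matches
better.  Networks are ranked by the training classification rate of
this rule; the top m networks are kept and vote on new samples.  The
apparent-accuracy difference of conservation indices between classes is
also reported per network as a secondary, non-selective ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    CLASS_1,
    CLASS_2,
    DataError,
    ExpressionDataset,
    Learner,
)
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 3
DEFAULT_M = 1


@dataclass
class RankTemplate:
    """Majority pairwise-ordering template of one network in one class."""

    network_name: str
    pair_list: list[tuple[str, str]]  # all C(n,2) pairs, network gene order
    bits: list[int]  # 1 iff gene_i > gene_j in the strict majority

    def to_dict(self) -> dict:
        return {
            "network_name": self.network_name,
            "pairs": [list(p) for p in self.pair_list],
            "bits": list(self.bits),
        }


@dataclass
class DIRACNetwork:
    name: str
    genes: list[str]  # genes present in the training dataset
    template1: RankTemplate
    template2: RankTemplate
    classification_rate: float
    conservation_gap: float  # |R(class1) - R(class2)|, secondary ordering


@dataclass
class DIRACClassifier:
    networks: list[DIRACNetwork]  # sorted by classification_rate desc
    m: int
    min_size: int
    class_priors: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "algorithm": "dirac",
            "m": self.m,
            "min_size": self.min_size,
            "class_priors": list(self.class_priors),
            "networks": [
                {
                    "name": n.name,
                    "genes": n.genes,
                    "template_class1": n.template1.to_dict(),
                    "template_class2": n.template2.to_dict(),
                    "classification_rate": n.classification_rate,
                    "conservation_gap": n.conservation_gap,
                }
                for n in self.networks
            ],
        }


def _present_genes(dataset: ExpressionDataset, network_genes: Sequence[str]) -> list[str]:
    known = set(dataset.gene_ids)
    return [g for g in network_genes if g in known]


def rank_template(
    dataset: ExpressionDataset,
    class_label: int,
    network_genes: Sequence[str],
    network_name: str = "",
) -> RankTemplate:
    """Majority template over all pairs of the network's present genes.

    The bit for pair (i, j) is 1 iff gene i exceeds gene j in strictly
    more than half of the class samples (per-sample ties count 0.5
    toward neither side; a fraction of exactly 0.5 yields bit 0, so the
    template is deterministic for even class sizes).
    """
    genes = _present_genes(dataset, network_genes)
    if len(genes) < 2:
        raise DataError(
            f"network {network_name or '?'} has {len(genes)} genes in the dataset; need >= 2"
        )
    x = dataset.class_matrix(class_label)
    if x.shape[1] == 0:
        raise DataError(f"class {class_label} has no samples")
    rows = {g: x[dataset.gene_index(g)] for g in genes}
    pair_list: list[tuple[str, str]] = []
    bits: list[int] = []
    for gi, gj in combinations(genes, 2):
        vi, vj = rows[gi], rows[gj]
        frac = ((vi > vj).sum() + 0.5 * (vi == vj).sum()) / x.shape[1]
        pair_list.append((gi, gj))
        bits.append(1 if frac > 0.5 else 0)
    return RankTemplate(network_name, pair_list, bits)


def rank_matching_score(sample_vector: Mapping[str, float], template: RankTemplate) -> float:
    """Fraction of template pairs the sample orders the same way.

    A tied pair in the sample matches neither orientation and counts 0.
    """
    matched = 0
    for (gi, gj), bit in zip(template.pair_list, template.bits):
        try:
            vi, vj = sample_vector[gi], sample_vector[gj]
        except KeyError as e:
            raise KeyError(f"sample vector missing gene {e.args[0]!r}") from None
        if vi > vj:
            matched += bit
        elif vi < vj:
            matched += 1 - bit
    return matched / len(template.pair_list)


def rank_conservation_index(
    dataset: ExpressionDataset, class_label: int, network_genes: Sequence[str]
) -> float:
    """Mean matching score of class samples against their own template."""
    template = rank_template(dataset, class_label, network_genes)
    ids = dataset.class_sample_ids(class_label)
    scores = [rank_matching_score(dataset.sample_vector(s), template) for s in ids]
    return float(np.mean(scores))


def _two_template_prediction(
    sample_vector: Mapping[str, float],
    template1: RankTemplate,
    template2: RankTemplate,
    class_priors: tuple[int, int],
) -> int:
    s1 = rank_matching_score(sample_vector, template1)
    s2 = rank_matching_score(sample_vector, template2)
    if s1 > s2:
        return CLASS_1
    if s2 > s1:
        return CLASS_2
    n1, n2 = class_priors
    return CLASS_1 if n1 >= n2 else CLASS_2


def network_classification_rate(
    dataset: ExpressionDataset, network_genes: Sequence[str]
) -> float:
    """Training accuracy of the network's nearest-template rule.

    Both class templates are built from the full training data; every
    labelled training sample is then assigned to the class whose
    template it matches better (ties to the larger class, then class 1).
    """
    dataset.require_two_classes()
    t1 = rank_template(dataset, CLASS_1, network_genes)
    t2 = rank_template(dataset, CLASS_2, network_genes)
    priors = dataset.class_sizes()
    labeled = dataset.labeled_sample_ids()
    correct = sum(
        1
        for s in labeled
        if _two_template_prediction(dataset.sample_vector(s), t1, t2, priors)
        == dataset.class_of[s]
    )
    return correct / len(labeled)


def train_dirac(
    dataset: ExpressionDataset,
    gene_sets: GeneSetCollection,
    params: Mapping | None = None,
) -> DIRACClassifier:
    """Score every eligible network and keep the top m.

    A network is eligible when at least ``min_size`` of its genes are
    present in the dataset.  Networks are ranked by training
    classification rate, ties broken by collection order; if fewer than
    m networks are eligible, all of them are kept (logged).
    """
    params = dict(params or {})
    min_size = int(params.get("min_size", DEFAULT_MIN_SIZE))
    m = int(params.get("m", DEFAULT_M))
    if m < 1:
        raise DataError("m must be >= 1")
    if min_size < 2:
        raise DataError("min_size must be >= 2")
    dataset.require_two_classes()
    priors = dataset.class_sizes()
    scored: list[DIRACNetwork] = []
    for gs in gene_sets:
        genes = _present_genes(dataset, gs.gene_ids)
        if len(genes) < min_size:
            logger.debug("network %s skipped: %d genes < min_size %d", gs.name, len(genes), min_size)
            continue
        t1 = rank_template(dataset, CLASS_1, genes, gs.name)
        t2 = rank_template(dataset, CLASS_2, genes, gs.name)
        rate = network_classification_rate(dataset, genes)
        gap = abs(
            rank_conservation_index(dataset, CLASS_1, genes)
            - rank_conservation_index(dataset, CLASS_2, genes)
        )
        scored.append(DIRACNetwork(gs.name, genes, t1, t2, rate, gap))
    if not scored:
        raise DataError(f"no network has >= {min_size} genes in the dataset")
    scored.sort(key=lambda n: -n.classification_rate)  # stable: collection order on ties
    if len(scored) < m:
        logger.info("only %d eligible networks (m=%d requested)", len(scored), m)
    kept = scored[:m]
    return DIRACClassifier(kept, len(kept), min_size, priors)


def classify_dirac(classifier: DIRACClassifier, sample_vector: Mapping[str, float]) -> int:
    """Each kept network votes by its nearest-template rule.

    A network whose two templates match the sample equally casts no
    vote; the majority of cast votes wins, overall ties falling back to
    the larger training class, then class 1.
    """
    votes1 = votes2 = 0
    for net in classifier.networks:
        s1 = rank_matching_score(sample_vector, net.template1)
        s2 = rank_matching_score(sample_vector, net.template2)
        if s1 > s2:
            votes1 += 1
        elif s2 > s1:
            votes2 += 1
    if votes1 > votes2:
        return CLASS_1
    if votes2 > votes1:
        return CLASS_2
    n1, n2 = classifier.class_priors
    return CLASS_1 if n1 >= n2 else CLASS_2


class DIRACLearner(Learner):
    """Learner-contract wrapper; ``params['gene_sets']`` supplies the GMT."""

    name = "dirac"

    def train(self, dataset, params=None):
        params = dict(params or {})
        gene_sets = params.pop("gene_sets", None)
        if gene_sets is None:
            raise DataError("DIRAC requires params['gene_sets'] (a GeneSetCollection)")
        return train_dirac(dataset, gene_sets, params)

    def classify(self, model, sample_vector):
        return classify_dirac(model, sample_vector)
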