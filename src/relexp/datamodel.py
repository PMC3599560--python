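"""Core data types shared by every relative-expression algorithm.

The central container is :class:`ExpressionDataset`, a genes x samples
real-valued table with two-class sample labels (class 1 and class 2;
class 1 is the "positive" class for confusion-matrix bookkeeping).
Samples without a label are carried along but excluded from every
training and cross-validation computation.

All four classifiers operate on within-sample gene *ranks*, never on
absolute expression values, which makes them invariant under any
strictly monotone per-sample transform (normalisation, log-scaling,
platform rescaling).  Ties in expression receive average ranks, the
standard rank-statistics convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

CLASS_1 = 1
CLASS_2 = 2
CLASS_LABELS = (CLASS_1, CLASS_2)


class DataError(ValueError):
    """Invalid dataset construction or use (bad labels, empty subset, ...)."""


class ExpressionDataset:
    """Real-valued genes x samples expression table with two-class labels.

    Parameters
    ----------
    gene_ids:
        Unique gene (or probe) identifiers, one per matrix row.
    sample_ids:
        Unique sample identifiers, one per matrix column.
    values:
        Expression matrix of shape ``(len(gene_ids), len(sample_ids))``,
        arbitrary units.  Genes constant across all samples are retained;
        they simply never win a reversal.
    class_of:
        Mapping ``sample_id -> 1 | 2`` for labelled samples.  Samples
        absent from the mapping are unassigned.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values,
        class_of: Mapping[str, int] | None = None,
    ):
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample identifiers")
        if not self.gene_ids or not self.sample_ids:
            raise DataError("dataset must contain at least one gene and one sample")
        self.class_of: dict[str, int] = {}
        if class_of:
            sample_set = set(self.sample_ids)
            for sid, label in class_of.items():
                if sid not in sample_set:
                    raise DataError(f"label for unknown sample {sid!r}")
                if label not in CLASS_LABELS:
                    raise DataError(f"class label must be 1 or 2, got {label!r}")
                self.class_of[sid] = int(label)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        """Expression values of one sample, in gene order."""
        return self.values[:, self.sample_index(sample_id)]

    def sample_vector(self, sample_id: str) -> dict[str, float]:
        """One sample as a ``gene_id -> value`` mapping (classifier input)."""
        col = self.column(sample_id)
        return {g: float(col[i]) for i, g in enumerate(self.gene_ids)}

    # -- labels ----------------------------------------------------------

    def labeled_sample_ids(self) -> list[str]:
        """Samples assigned to class 1 or 2, in dataset order."""
        return [s for s in self.sample_ids if s in self.class_of]

    def class_sample_ids(self, label: int) -> list[str]:
        if label not in CLASS_LABELS:
            raise DataError(f"class label must be 1 or 2, got {label!r}")
        return [s for s in self.sample_ids if self.class_of.get(s) == label]

    def class_matrix(self, label: int) -> np.ndarray:
        """Genes x class-samples value matrix for one class."""
        idx = [self._sample_index[s] for s in self.class_sample_ids(label)]
        return self.values[:, idx]

    def class_sizes(self) -> tuple[int, int]:
        return (len(self.class_sample_ids(CLASS_1)), len(self.class_sample_ids(CLASS_2)))

    def require_two_classes(self) -> None:
        n1, n2 = self.class_sizes()
        if n1 == 0 or n2 == 0:
            raise DataError(
                f"training requires samples in both classes (have {n1} in class 1, {n2} in class 2)"
            )

    def with_classes(self, class_of: Mapping[str, int]) -> "ExpressionDataset":
        """New dataset sharing values with the given label assignment."""
        return ExpressionDataset(self.gene_ids, self.sample_ids, self.values, class_of)

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the named samples (in the given order).

        Gene order is preserved and class labels are carried through.
        """
        ids = list(sample_ids)
        if not ids:
            raise DataError("cannot subset to zero samples")
        idx = [self.sample_index(s) for s in ids]
        labels = {s: self.class_of[s] for s in ids if s in self.class_of}
        return ExpressionDataset(self.gene_ids, ids, self.values[:, idx], labels)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the named genes (in the given order); labels kept."""
        ids = list(gene_ids)
        if not ids:
            raise DataError("cannot subset to zero genes")
        idx = [self.gene_index(g) for g in ids]
        return ExpressionDataset(ids, self.sample_ids, self.values[idx, :], self.class_of)

    # -- equality (used by round-trip tests) -----------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
            and self.class_of == other.class_of
        )

    def __repr__(self) -> str:
        n1, n2 = self.class_sizes()
        return (
            f"ExpressionDataset({self.n_genes} genes x {self.n_samples} samples, "
            f"class sizes {n1}/{n2})"
        )


@dataclass
class SampleRanking:
    """Within-sample gene ranks: rank 1 = lowest expression, ties averaged.

    Over ``n`` genes the ranks always sum to ``n(n+1)/2``.
    """

    sample_id: str
    ranks: dict[str, float] = field(default_factory=dict)


def rank_sample(dataset: ExpressionDataset, sample_id: str) -> SampleRanking:
    """Rank one sample's expression values (1 = smallest, average ties)."""
    col = dataset.column(sample_id)
    r = rankdata(col, method="average")
    return SampleRanking(sample_id, {g: float(r[i]) for i, g in enumerate(dataset.gene_ids)})


def rank_matrix(dataset: ExpressionDataset) -> np.ndarray:
    """Within-sample average ranks for every sample; shape genes x samples."""
    return rankdata(dataset.values, method="average", axis=0)


class Learner:
    """Uniform contract implemented by all four classifiers.

    Every learner provides ``train(dataset, params) -> model``,
    ``classify(model, sample_vector) -> 1 | 2`` and
    ``cross_validate(dataset, params, folds, repeats, seed)``, so the
    evaluation and adaptive layers can drive any algorithm through one
    interface.
    """

    name: str = "abstract"

    def train(self, dataset: ExpressionDataset, params: Mapping | None = None):
        raise NotImplementedError

    def classify(self, model, sample_vector: Mapping[str, float]) -> int:
        raise NotImplementedError

    def cross_validate(
        self,
        dataset: ExpressionDataset,
        params: Mapping | None = None,
        folds: int = 10,
        repeats: int = 10,
        seed: int = 0,
    ):
        from .evaluation import cross_validate

        return cross_validate(dataset, self, params, k=folds, repeats=repeats, seed=seed)
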