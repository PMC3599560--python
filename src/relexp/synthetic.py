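"""Synthetic two-class expression data with planted rank signals.

The generator emulates, at desk scale, the structure of a curated
two-class microarray comparison: a genes x samples table whose
background genes are exchangeable noise around per-gene baselines,
with optional planted signals of the three kinds the classifiers
detect:

* ``PairReversal`` — a gene pair whose ordering flips between classes
  (the TSP signal): before noise, gene i sits ``gap`` above gene j in
  class 1 and ``gap`` below it in class 2.
* ``TripleCycle`` — each class-1 sample orders a gene triple by one of
  the three cyclic permutations, each class-2 sample by one of the
  three anti-cyclic ones (chosen uniformly).  The class ordering
  distributions have disjoint support, so the triple's TV score is 1
  while every pairwise Delta inside it is capped at 1/3 — the cleanest
  TSP-vs-TST separation.
* ``NetworkRerank`` — a named gene set expressed as a fixed descending
  value ladder in class 1 and the reversed ladder in class 2 (the
  DIRAC signal).

Planted levels are spaced ``ladder_sd_multiple`` noise standard
deviations apart (default 6), so noise essentially never flips a
planted ordering.  Each signal kind lives in its own value band —
the pair below the baseline range, the triple inside it, the network
ladder above it — so a planted reversal never accidentally extends to
background genes and the planted structure is the unique maximal one
of its kind.  Everything is deterministic given the seed.  Noise
is Gaussian on the raw scale — rank methods are insensitive to the
marginal distribution — with an optional exponentiation to a lognormal
scale mimicking expression units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .datamodel import CLASS_1, CLASS_2, DataError, ExpressionDataset
from .io_formats import (
    CohortMap,
    GeneSet,
    GeneSetCollection,
    write_csv_expression,
    write_gmt,
    write_soft,
)

#: ascending-order triples: cyclic orderings of (i, j, k) for class 1 ...
CYCLIC = ((0, 1, 2), (1, 2, 0), (2, 0, 1))
#: ... and the anti-cyclic orderings for class 2
ANTI_CYCLIC = ((0, 2, 1), (1, 0, 2), (2, 1, 0))


@dataclass(frozen=True)
class PairReversal:
    gene_i: int
    gene_j: int
    gap: float = 6.0

    def genes(self) -> tuple[int, ...]:
        return (self.gene_i, self.gene_j)


@dataclass(frozen=True)
class TripleCycle:
    gene_i: int
    gene_j: int
    gene_k: int

    def genes(self) -> tuple[int, ...]:
        return (self.gene_i, self.gene_j, self.gene_k)


@dataclass(frozen=True)
class NetworkRerank:
    network_name: str
    genes_idx: tuple[int, ...]

    def genes(self) -> tuple[int, ...]:
        return tuple(self.genes_idx)


Signal = Union[PairReversal, TripleCycle, NetworkRerank]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small balanced two-class comparison: 50 genes,
    20 samples per class, unit noise.
    """

    n_genes: int = 50
    n_samples_per_class: int = 20
    noise_sd: float = 1.0
    planted: tuple[Signal, ...] = ()
    seed: int = 0
    ladder_sd_multiple: float = 6.0  # spacing of planted levels, in noise SDs
    n_decoy_networks: int = 9
    decoy_network_size: int = 4
    baseline_range: tuple[float, float] = (5.0, 10.0)
    lognormal: bool = False

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_class < 1:
            raise DataError("n_genes and n_samples_per_class must be positive")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if self.ladder_sd_multiple < 3.0:
            raise DataError("ladder_sd_multiple must be >= 3")
        used: set[int] = set()
        for sig in self.planted:
            g = sig.genes()
            if isinstance(sig, PairReversal) and sig.gap <= 0:
                raise DataError("pair reversal gap must be positive")
            if len(set(g)) != len(g):
                raise DataError(f"signal {sig} repeats a gene")
            if any(not 0 <= i < self.n_genes for i in g):
                raise DataError(f"signal {sig} references a gene outside [0, {self.n_genes})")
            clash = used & set(g)
            if clash:
                raise DataError(f"contradictory signals: genes {sorted(clash)} planted twice")
            used.update(g)


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GeneSetCollection]:
    """Draw one dataset (and its gene-set collection) from the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g, m = spec.n_genes, spec.n_samples_per_class
    lo, hi = spec.baseline_range
    baselines = rng.uniform(lo, hi, size=g)
    pre = np.tile(baselines[:, None], (1, 2 * m))  # class 1 cols then class 2
    c1 = slice(0, m)
    c2 = slice(m, 2 * m)
    spacing = spec.ladder_sd_multiple * spec.noise_sd
    center = (lo + hi) / 2.0

    for sig in spec.planted:
        if isinstance(sig, PairReversal):
            # reserved band below the baselines: the reversal stays
            # internal to the pair instead of sweeping across noise genes
            pivot = lo - sig.gap - spacing
            pre[sig.gene_i, c1] = pivot + sig.gap / 2.0
            pre[sig.gene_j, c1] = pivot - sig.gap / 2.0
            pre[sig.gene_i, c2] = pivot - sig.gap / 2.0
            pre[sig.gene_j, c2] = pivot + sig.gap / 2.0
        elif isinstance(sig, TripleCycle):
            tri = (sig.gene_i, sig.gene_j, sig.gene_k)
            levels = center + spacing * np.array([-1.0, 0.0, 1.0])
            for col in range(2 * m):
                fam = CYCLIC if col < m else ANTI_CYCLIC
                order = fam[rng.integers(len(fam))]
                # order lists gene slots in ascending value
                for level, slot in zip(levels, order):
                    pre[tri[slot], col] = level
        elif isinstance(sig, NetworkRerank):
            # reserved band above the baselines, for the same reason
            n = len(sig.genes_idx)
            ladder = hi + spacing * np.arange(n, 0, -1)
            for pos, gi in enumerate(sig.genes_idx):
                pre[gi, c1] = ladder[pos]
                pre[gi, c2] = ladder[n - 1 - pos]
        else:  # pragma: no cover - guarded by validate
            raise DataError(f"unknown signal type {sig!r}")

    values = pre + rng.normal(0.0, spec.noise_sd, size=pre.shape)
    if spec.lognormal:
        values = np.exp(values / (hi - lo))

    gene_ids = [_gene_name(i) for i in range(g)]
    sample_ids = [f"C1_S{j + 1:03d}" for j in range(m)] + [
        f"C2_S{j + 1:03d}" for j in range(m)
    ]
    labels = {s: CLASS_1 for s in sample_ids[:m]}
    labels.update({s: CLASS_2 for s in sample_ids[m:]})
    dataset = ExpressionDataset(gene_ids, sample_ids, values, labels)

    sets: list[GeneSet] = []
    planted_gene_idx: set[int] = set()
    for sig in spec.planted:
        planted_gene_idx.update(sig.genes())
        if isinstance(sig, NetworkRerank):
            sets.append(
                GeneSet(
                    sig.network_name,
                    "planted reranking network",
                    [_gene_name(i) for i in sig.genes_idx],
                )
            )
    background = [i for i in range(g) if i not in planted_gene_idx]
    size = min(spec.decoy_network_size, max(len(background), 2))
    for d in range(spec.n_decoy_networks):
        if len(background) < 2:
            break
        pick = rng.choice(background, size=min(size, len(background)), replace=False)
        sets.append(
            GeneSet(
                f"DECOY_{d + 1:02d}",
                "background genes",
                [_gene_name(int(i)) for i in sorted(pick)],
            )
        )
    return dataset, GeneSetCollection(sets)


def default_fixture_spec(seed: int = 0) -> SyntheticSpec:
    """Canonical fixture: one planted signal of each kind plus decoys."""
    return SyntheticSpec(
        n_genes=30,
        n_samples_per_class=20,
        noise_sd=1.0,
        planted=(
            PairReversal(0, 1, gap=6.0),
            TripleCycle(2, 3, 4),
            NetworkRerank("PLANTED_NET", (5, 6, 7, 8)),
        ),
        seed=seed,
    )


def write_fixture_suite(directory, spec: SyntheticSpec | None = None) -> dict:
    """Write the canonical CSV/SOFT/GMT fixture suite plus a manifest.

    The SOFT file mirrors the cohort workflow: class-1 samples carry
    the ``normal`` subset tag and class-2 samples the ``cancer`` tag.
    Returns (and writes) a manifest listing the planted, recoverable
    signals.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = spec or default_fixture_spec()
    dataset, gene_sets = generate(spec)

    write_csv_expression(dataset, directory / "expression.csv")
    cohorts = CohortMap(
        {
            "normal": dataset.class_sample_ids(CLASS_1),
            "cancer": dataset.class_sample_ids(CLASS_2),
        }
    )
    write_soft(dataset, cohorts, directory / "expression.soft")
    if len(gene_sets):
        write_gmt(gene_sets, directory / "networks.gmt")

    manifest: dict = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "n_samples_per_class": spec.n_samples_per_class,
        "files": {
            "csv": "expression.csv",
            "soft": "expression.soft",
            "gmt": "networks.gmt" if len(gene_sets) else None,
        },
        "cohorts": {"class1": "normal", "class2": "cancer"},
        "planted": [],
    }
    for sig in spec.planted:
        if isinstance(sig, PairReversal):
            manifest["planted"].append(
                {
                    "kind": "pair_reversal",
                    "genes": [_gene_name(sig.gene_i), _gene_name(sig.gene_j)],
                    "gap": sig.gap,
                }
            )
        elif isinstance(sig, TripleCycle):
            manifest["planted"].append(
                {
                    "kind": "triple_cycle",
                    "genes": [_gene_name(i) for i in sig.genes()],
                }
            )
        elif isinstance(sig, NetworkRerank):
            manifest["planted"].append(
                {
                    "kind": "network_rerank",
                    "network": sig.network_name,
                    "genes": [_gene_name(i) for i in sig.genes_idx],
                }
            )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
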