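"""Adaptive search over Algorithm-Parameter Configurations (APCs).

An APC is one algorithm plus one concrete parameter setting (e.g. TSP
with a 50-gene filter, or DIRAC with min_size 3 and m 5).  The search
repeatedly runs the APC with the smallest selection score

    delta(x) = t(x) / prod over past runs y of the same algorithm of alpha(y)

where t(x) is a deterministic abstract cost estimate and alpha(y) is
the linear mapping of a past run's cross-validated MCC into (0, 1)
(clamped away from the endpoints).  This makes an APC more likely to
run when it is cheap, its algorithm has run few times, and its
algorithm scored well before.  A product form ``t(x) * prod alpha(y)``
— which instead *rewards* frequent running and *punishes* good scores —
is selectable via ``mode="literal"`` for comparison; the quotient form
is the default because it is the one consistent with all three
intended monotonicities.

Costs are abstract units (pair search ~ filter_n^2 * samples, triple
search ~ filter_n^3 * samples, DIRAC ~ samples * total template pairs),
so the budget and the run order are hardware-independent and exactly
reproducible from a seed.  The search stops when the unit budget is
exhausted, the grid is exhausted, or a run reaches the target CV MCC
(default 1.0, i.e. perfect cross-validated accuracy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .datamodel import DataError, ExpressionDataset
from .dirac import DEFAULT_MIN_SIZE, _present_genes
from .evaluation import EvaluationResult, cross_validate
from .io_formats import GeneSetCollection
from .learners import get_learner

logger = logging.getLogger(__name__)

ALPHA_EPS = 1e-6

DEFAULT_FILTER_GRID = (25, 50, 100, 200)
DEFAULT_KMAX_GRID = (5, 9)
DEFAULT_MIN_SIZE_GRID = (3, 5)
DEFAULT_M_GRID = (1, 3, 5)
TST_FILTER_CAP = 200


@dataclass(frozen=True)
class APC:
    """One algorithm-parameter configuration."""

    algorithm: str
    parameters: tuple[tuple[str, int], ...]  # sorted (name, value) pairs

    @classmethod
    def make(cls, algorithm: str, **parameters: int) -> "APC":
        return cls(algorithm, tuple(sorted(parameters.items())))

    def param_dict(self) -> dict[str, int]:
        return dict(self.parameters)

    def __str__(self) -> str:
        ps = ",".join(f"{k}={v}" for k, v in self.parameters)
        return f"{self.algorithm}({ps})"


@dataclass
class AdaptiveRun:
    """One executed APC with its selection-time score and outcome."""

    apc: APC
    delta: float
    cost: float
    mean_mcc: float
    alpha: float
    result: EvaluationResult


@dataclass
class AdaptiveHistory:
    """Per-algorithm record of past runs' alpha values."""

    alphas: dict[str, list[float]] = field(default_factory=dict)

    def record(self, algorithm: str, alpha: float) -> None:
        self.alphas.setdefault(algorithm, []).append(alpha)

    def for_algorithm(self, algorithm: str) -> list[float]:
        return self.alphas.get(algorithm, [])


@dataclass
class AdaptiveResult:
    best_apc: APC
    best_result: EvaluationResult
    trained_model: object
    runs: list[AdaptiveRun]

    def to_dict(self) -> dict:
        return {
            "best_apc": {"algorithm": self.best_apc.algorithm, **self.best_apc.param_dict()},
            "best_mean_mcc": self.best_result.mean_mcc,
            "runs": [
                {
                    "algorithm": r.apc.algorithm,
                    **r.apc.param_dict(),
                    "delta": r.delta,
                    "cost": r.cost,
                    "mean_mcc": r.mean_mcc,
                    "alpha": r.alpha,
                }
                for r in self.runs
            ],
        }


def estimate_cost(
    apc: APC,
    dataset: ExpressionDataset,
    gene_sets: GeneSetCollection | None = None,
) -> float:
    """Deterministic abstract cost of running one APC.

    Pair search scales with filter_n^2, the triple search with
    filter_n^3, DIRAC with the total number of template pairs across
    eligible networks; all scale with the number of labelled samples.
    """
    m_samples = len(dataset.labeled_sample_ids()) or dataset.n_samples
    p = apc.param_dict()
    if apc.algorithm in ("tsp", "ktsp"):
        n = min(p.get("filter_n", dataset.n_genes), dataset.n_genes)
        return float(n * n * m_samples)
    if apc.algorithm == "tst":
        n = min(p.get("filter_n", TST_FILTER_CAP), dataset.n_genes)
        return float(n * n * n * m_samples)
    if apc.algorithm == "dirac":
        if gene_sets is None:
            raise DataError("DIRAC cost estimate requires gene sets")
        min_size = p.get("min_size", DEFAULT_MIN_SIZE)
        pairs = 0
        for gs in gene_sets:
            n_g = len(_present_genes(dataset, gs.gene_ids))
            if n_g >= min_size:
                pairs += n_g * (n_g - 1) // 2
        return float(m_samples * pairs) if pairs else 0.0
    raise DataError(f"unknown algorithm {apc.algorithm!r}")


def alpha_of_mcc(mcc_value: float) -> float:
    """Linear map of MCC from [-1, 1] onto (0, 1), clamped at 1e-6."""
    if not -1.0 <= mcc_value <= 1.0:
        raise DataError(f"MCC must lie in [-1, 1], got {mcc_value}")
    return min(max((mcc_value + 1.0) / 2.0, ALPHA_EPS), 1.0 - ALPHA_EPS)


def delta(apc_cost: float, history_alphas: Sequence[float], mode: str = "quotient") -> float:
    """Selection score of an APC given its algorithm's past alphas.

    ``quotient`` (default): cost divided by the product of past alphas —
    grows with cost and with the number of past runs, shrinks as past
    scores improve.  ``literal``: cost times the product of past alphas.
    """
    prod = 1.0
    for a in history_alphas:
        prod *= a
    if mode == "quotient":
        return apc_cost / prod
    if mode == "literal":
        return apc_cost * prod
    raise DataError(f"unknown delta mode {mode!r}")


def default_grid(
    dataset: ExpressionDataset, gene_sets: GeneSetCollection | None = None
) -> list[APC]:
    """Default APC grid over the tunable dimensions of each algorithm.

    filter_n in {25, 50, 100, 200} for tsp/ktsp/tst (values above the
    dataset's gene count are dropped, keeping at least one); k_max in
    {5, 9}; DIRAC min_size in {3, 5} crossed with m in {1, 3, 5}
    (only when gene sets are provided).
    """
    g = dataset.n_genes
    filters = [n for n in DEFAULT_FILTER_GRID if n <= g] or [g]
    grid: list[APC] = []
    for n in filters:
        grid.append(APC.make("tsp", filter_n=n))
    for n in filters:
        for k_max in DEFAULT_KMAX_GRID:
            grid.append(APC.make("ktsp", filter_n=n, k_max=k_max))
    for n in filters:
        if n <= TST_FILTER_CAP:
            grid.append(APC.make("tst", filter_n=n))
    if gene_sets is not None:
        for min_size in DEFAULT_MIN_SIZE_GRID:
            for m in DEFAULT_M_GRID:
                grid.append(APC.make("dirac", min_size=min_size, m=m))
    return grid


def adaptive_search(
    dataset: ExpressionDataset,
    gene_sets: GeneSetCollection | None = None,
    apc_grid: Sequence[APC] | None = None,
    budget_units: float = 1e9,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    mode: str = "quotient",
    target_mcc: float = 1.0,
) -> AdaptiveResult:
    """Run minimum-delta APCs until the budget, grid, or target is hit.

    Each iteration recomputes delta for every not-yet-run APC, runs the
    argmin (ties: algorithm name alphabetical, then parameter tuple
    ascending) through repeated stratified CV, records the run's alpha
    in its algorithm's history, and deducts its cost from the budget.
    The best APC by mean CV MCC is finally retrained on the full
    labelled data.  Everything is deterministic given the seed.
    """
    if budget_units <= 0:
        raise DataError("budget must be positive")
    dataset.require_two_classes()
    grid = list(apc_grid) if apc_grid is not None else default_grid(dataset, gene_sets)
    costed: list[tuple[APC, float]] = []
    for apc in grid:
        c = estimate_cost(apc, dataset, gene_sets)
        if c <= 0:
            logger.info("dropping %s: no eligible work (cost 0)", apc)
            continue
        costed.append((apc, c))
    if not costed:
        raise DataError("APC grid is empty after eligibility filtering")

    history = AdaptiveHistory()
    runs: list[AdaptiveRun] = []
    remaining = list(costed)
    budget = float(budget_units)
    while remaining and budget > 0:
        scored = [
            (delta(cost, history.for_algorithm(apc.algorithm), mode), apc, cost)
            for apc, cost in remaining
        ]
        scored.sort(key=lambda t: (t[0], t[1].algorithm, t[1].parameters))
        d, apc, cost = scored[0]
        remaining = [(a, c) for a, c in remaining if a != apc]

        params = apc.param_dict()
        params["seed"] = seed
        if apc.algorithm == "dirac":
            params["gene_sets"] = gene_sets
        result = cross_validate(
            dataset, get_learner(apc.algorithm), params, k=folds, repeats=repeats, seed=seed
        )
        a = alpha_of_mcc(result.mean_mcc)
        history.record(apc.algorithm, a)
        runs.append(AdaptiveRun(apc, d, cost, result.mean_mcc, a, result))
        budget -= cost
        logger.info("ran %s: delta=%.3g mean_mcc=%.3f budget left %.3g", apc, d, result.mean_mcc, budget)
        if result.mean_mcc >= target_mcc:
            logger.info("target MCC %.3f reached by %s; stopping", target_mcc, apc)
            break

    best = max(runs, key=lambda r: r.mean_mcc)
    params = best.apc.param_dict()
    params["seed"] = seed
    if best.apc.algorithm == "dirac":
        params["gene_sets"] = gene_sets
    model = get_learner(best.apc.algorithm).train(dataset, params)
    return AdaptiveResult(best.apc, best.result, model, runs)
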