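# Methods

This note records the statistical definitions the package implements,
the conventions chosen where the methods' descriptions in the
literature leave details open, and what the synthetic benchmarks do and
do not demonstrate.

## Data model and rank transform

A dataset is a real-valued genes × samples matrix with unique gene and
sample identifiers and a partial labelling of samples into class 1 and
class 2 (class 1 is the positive class for confusion-matrix
bookkeeping).  Unlabelled samples are carried through I/O and merging
but excluded from every training and cross-validation computation.
Within-sample ranks use the average-rank convention for ties (rank 1 =
lowest expression), the standard choice in rank statistics; it makes
every downstream quantity deterministic.  Genes constant across all
samples are retained — they can never win a reversal, so dropping them
would only change tie-breaking.

Missing or non-numeric expression cells are parse errors, never
imputed: rank statistics have no natural missing-value semantics, and
silent imputation would alter orderings invisibly.

## Estimators and tie conventions

All order probabilities are empirical within-class frequencies with
ties contributing ½:

* `p_c(i, j) = P(X_i < X_j | class c)` — a sample with `X_i = X_j`
  counts ½.  The TSP score is `Δ = |p₁ − p₂| ∈ [0, 1]`.
* A triple's six-ordering distribution — a sample with tied values
  splits its mass equally over the orderings compatible with its weak
  ordering.  The TST score is the total-variation distance
  `½ Σ_π |p₁(π) − p₂(π)| ∈ [0, 1]`.  TV was chosen because it reduces
  to the TSP `Δ` when a triple is projected onto a pair and has a fixed
  [0, 1] range; the unnormalised sum of absolute differences is the
  same statistic times two and would order triples identically.
* DIRAC template bits — the bit for pair (i, j) is 1 iff `X_i > X_j` in
  strictly more than half of the class's samples (per-sample ties count
  ½ toward neither side); a fraction of exactly ½ gives bit 0, so
  templates are deterministic for even class sizes.  A tied pair in a
  scored sample matches neither template orientation.

Deterministic tie cascades make training reproducible and equal to
brute-force enumeration: pairs are ordered by (Δ desc, Γ desc,
lexicographic), where the secondary score
`Γ = |(r̄₁ᵢ − r̄₂ᵢ) − (r̄₁ⱼ − r̄₂ⱼ)|` (difference of mean within-sample
rank gaps between classes) follows the k-TSP tradition of breaking
score ties by rank separation; triples tie lexicographically.  Inside
the triple search the per-triple score is computed in integer
arithmetic (tie splits are multiples of 1/6), so score ties are exact
rather than float-dependent.

Classification tie rules, in order: an exactly tied comparison in the
query sample falls back to the larger training class, then class 1;
a TST query ordering unseen in both classes falls back the same way;
a DIRAC network whose two templates match a query equally casts no
vote.

## Gene filter

The pre-filter scores each gene with the centred two-sample Wilcoxon
rank-sum (Mann–Whitney) statistic `|U − n₁n₂/2|` (ties 0.5) and keeps
the top n, ties broken by gene order.  Only the induced ranking
matters, so no p-value or normal approximation is involved.  The
comparison here is between two independent sample groups, so the
two-sample rank-sum form is used (a signed-rank test would require
paired samples, which class-partitioned expression data are not).  The
filter is refit on the training side of every cross-validation fold;
filtering once on the full dataset would leak held-out labels into the
signature and inflate CV accuracy.

## k-TSP

k is restricted to odd values in {1, 3, …, k_max} (default k_max 10) so
the majority vote cannot tie.  Pairs are selected greedily from the
ranked list under the one-gene-one-pair constraint; if fewer than k
disjoint pairs exist the list is trimmed to the largest odd count
("k or less").  k itself is chosen by stratified inner cross-validation
(default 5 folds, lowered with a log notice when a class is smaller),
with the inner confusion matrix pooled over folds into one MCC per
candidate and ties going to the smallest k.  Pair ranking and gene
filtering are refit inside every inner fold for the same
selection-bias reason as above.

## DIRAC

Networks are intersected with the measured genes before the minimum
size test (default `min_size` 3), since gene-set files routinely list
unmeasured genes.  Networks are ranked for selection by the training
classification rate of the two-template rule, which directly targets
classification; the absolute difference of within-class rank
conservation indices is also computed per kept network as a secondary,
non-selective ordering.  The top `m` networks (default 1) vote on new
samples.

## Cross-validation and MCC

Folds are stratified (per-class counts differ by at most one across
folds) because the typical class sizes in two-class expression studies
would otherwise produce single-class training folds.  Each repeat r
draws folds from `seed + r`; the confusion matrix is pooled across the
folds of one repeat before computing MCC, because MCC on a 2–4 sample
fold is frequently undefined.  Summaries are the mean and (sample)
standard deviation over repeats; a single repeat reports sd 0 by
convention.  MCC uses the standard zero-denominator convention
(any empty margin ⇒ 0), which also makes the adaptive α mapping total.
Defaults are 10 folds × 10 repeats.

## Adaptive search

The selection score combines a deterministic cost estimate with the
algorithm's history of cross-validated scores.  Cost is expressed in
abstract units — `filter_n²·M` for pair search, `filter_n³·M` for the
triple search, `M · Σ_networks C(n_g, 2)` for DIRAC, with M the number
of labelled samples — rather than wall-clock time, so run order and
budget accounting are hardware-independent and exactly reproducible
from a seed.

Two δ forms are implemented.  The default is the quotient
`δ = t(x) / Π α(y)`: it increases with cost, increases with each
additional past run (every α < 1), and decreases when a past run scored
better — exactly the three intended monotonicities of the selection
heuristic.  The product form `δ = t(x) · Π α(y)` is available as
`mode="literal"` for comparison; taken literally it would favour
algorithms that have run often and scored badly, contradicting two of
those three properties, which is why it is not the default.  α maps MCC
linearly onto (0, 1) and is clamped to [10⁻⁶, 1 − 10⁻⁶] so a perfect or
pathological run cannot freeze the product at 0 or 1.

History is keyed by algorithm, not by APC: every past run of, say, TSP
informs the δ of every TSP configuration.  The stop conditions are an
exhausted unit budget, an exhausted grid, or a run reaching the target
mean CV MCC (default 1.0, i.e. perfect cross-validated accuracy; the
target is configurable).  The best APC by mean CV MCC is finally
retrained on the full labelled data.  The default grid spans
filter_n ∈ {25, 50, 100, 200} (triple search capped at 200 genes,
values above the dataset's gene count dropped), k_max ∈ {5, 9}, and
DIRAC min_size ∈ {3, 5} × m ∈ {1, 3, 5}.

## Synthetic data

The generator emulates a curated two-class expression comparison at
desk scale: per-gene baselines drawn uniformly from [5, 10], i.i.d.
Gaussian noise (default sd 1), balanced classes of 20 samples each,
and optional planted signals:

* **pair reversal** — the pair's pre-noise values sit `gap` apart and
  swap between classes;
* **triple cycle** — each class-1 sample's triple ordering is drawn
  uniformly from the three cyclic permutations and each class-2
  sample's from the three anti-cyclic ones, giving ordering
  distributions with disjoint support (TV = 1) while capping every
  pairwise Δ inside the triple at 1/3 in expectation — the cleanest
  construction separating what TST can see from what TSP can;
* **network rerank** — the network's genes form a fixed descending
  value ladder in class 1, reversed in class 2.

Planted levels are spaced 6 noise standard deviations apart, so noise
flips a planted ordering with probability ≈ 10⁻⁵ per comparison and
planted recoveries are exact at the default sample sizes.  Each signal
kind occupies its own value band (pair below the baseline range, triple
inside it, network above it); this keeps a planted reversal internal to
its own genes — without the separation, a strongly shifted planted gene
sweeps across noise baselines and creates many additional perfect
reversals, making "the" top pair ill-defined.  Gaussian noise is
sufficient because every statistic in the package depends on
within-sample order only; an optional exponentiation produces a
lognormal value scale without changing any rank.

What passing these benchmarks shows: the searches find exactly the
optima they define, signals that are perfectly rank-separated are
recovered with perfect cross-validated MCC, and label-independent data
yields near-zero MCC.  What they do not show: performance under
realistic microarray noise (probe effects, batch structure,
normalisation artifacts, correlated genes), behaviour at transcriptome
scale, or accuracy on any real phenotype comparison.

## Problem sizes in tests and the acceptance script

Brute-force equivalence is checked on random datasets of up to 30 genes
(pairs) and 8 genes (triples) with class sizes of 4–16 — sizes at which
exact rational enumeration is itself fast — 240 datasets in the test
suite and 200 in the acceptance script.  Power-of-two class sizes make
the empirical order probabilities exactly representable in binary
floating point, so implementation and oracle can be compared for exact
equality rather than within a tolerance.  Planted-recovery checks use
20–30 genes and 20–30 samples per class with the full 10×10-fold CV
protocol; the null check uses 20 genes and 40 samples.  These sizes are
the package's chosen desk-scale study conditions: large enough for the
planted/null contrasts to be sharp, small enough that the whole
acceptance run completes in seconds.

## Known limitations

* Two classes only; multi-class problems must be decomposed externally.
* Dataset merging intersects exact gene identifiers; no cross-platform
  probe mapping or probe-to-symbol collapsing is performed, so merging
  different array platforms requires pre-harmonised identifiers.
* SOFT support targets the GDS dataset-table layout (the one carrying
  subset cohort tags); GSE family files are out of scope.
* The triple search is O(G³) and intended to run behind the gene
  filter (default cap 200 genes), not on a full transcriptome.
* No significance testing of Δ or of accuracy differences is provided.
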