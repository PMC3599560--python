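"""Independent brute-force oracles, written against the definitions only.

These enumerate every pair / triple with exact rational arithmetic
(fractions.Fraction) and pure-Python loops, sharing no code with the
package's search implementations.
"""

from fractions import Fraction
from itertools import combinations, permutations

from relexp.datamodel import CLASS_1, CLASS_2


def _class_columns(dataset, label):
    idx = [dataset.sample_index(s) for s in dataset.class_sample_ids(label)]
    return [[float(dataset.values[g, j]) for j in idx] for g in range(dataset.n_genes)]


def _avg_ranks(column_values):
    """Average ranks (1 = smallest) of one sample's values."""
    n = len(column_values)
    ranks = []
    for v in column_values:
        below = sum(1 for w in column_values if w < v)
        ties = sum(1 for w in column_values if w == v)
        ranks.append(Fraction(2 * below + ties + 1, 2))
    return ranks


def brute_force_tsp(dataset):
    """Best pair by (Delta desc, Gamma desc, lexicographic) — exact."""
    g = dataset.n_genes
    x1 = _class_columns(dataset, CLASS_1)
    x2 = _class_columns(dataset, CLASS_2)
    m1, m2 = len(x1[0]), len(x2[0])

    def p_less(cols, i, j, m):
        num = Fraction(0)
        for s in range(m):
            if cols[i][s] < cols[j][s]:
                num += 1
            elif cols[i][s] == cols[j][s]:
                num += Fraction(1, 2)
        return num / m

    # mean within-sample rank per gene and class
    def mean_ranks(cols, m):
        per_sample = [_avg_ranks([cols[i][s] for i in range(g)]) for s in range(m)]
        return [sum(per_sample[s][i] for s in range(m)) / m for i in range(g)]

    r1 = mean_ranks(x1, m1)
    r2 = mean_ranks(x2, m2)
    best = None
    for i in range(g):
        for j in range(i + 1, g):
            delta = abs(p_less(x1, i, j, m1) - p_less(x2, i, j, m2))
            gamma = abs((r1[i] - r2[i]) - (r1[j] - r2[j]))
            key = (delta, gamma)
            if best is None or key > best[0]:
                best = (key, i, j)
    (delta, gamma), i, j = best
    return dataset.gene_ids[i], dataset.gene_ids[j], delta, gamma


def _ordering_freqs(cols, genes, m):
    """Exact frequency of each of the 6 ascending orderings of a triple."""
    perms = list(permutations(range(3)))
    freqs = [Fraction(0)] * 6
    for s in range(m):
        vals = [cols[genes[t]][s] for t in range(3)]
        compat = [
            t
            for t, p in enumerate(perms)
            if vals[p[0]] <= vals[p[1]] <= vals[p[2]]
        ]
        for t in compat:
            freqs[t] += Fraction(1, len(compat))
    return [f / m for f in freqs]


def brute_force_tst(dataset):
    """Best triple by (TV score desc, lexicographic) — exact."""
    g = dataset.n_genes
    x1 = _class_columns(dataset, CLASS_1)
    x2 = _class_columns(dataset, CLASS_2)
    m1, m2 = len(x1[0]), len(x2[0])
    best = None
    for tri in combinations(range(g), 3):
        f1 = _ordering_freqs(x1, tri, m1)
        f2 = _ordering_freqs(x2, tri, m2)
        tv = sum(abs(a - b) for a, b in zip(f1, f2)) / 2
        if best is None or tv > best[0]:
            best = (tv, tri)
    tv, tri = best
    return tuple(dataset.gene_ids[t] for t in tri), tv
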