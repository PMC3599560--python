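import numpy as np
import pytest

from relexp.datamodel import CLASS_1, CLASS_2, DataError
from relexp.tsp import pair_score
from relexp.tst import (
    PERMS,
    classify_tst,
    ordering_distribution,
    sample_permutation,
    train_tst,
    tst_score,
)

from conftest import cyclic_triple_dataset, make_dataset, random_dataset
from oracles import brute_force_tst


class TestOrderingDistribution:
    def test_single_ordering(self):
        ds = make_dataset([[1, 1], [2, 2], [3, 3]], class1_count=2)
        dist = ordering_distribution(ds, CLASS_1, ("g0", "g1", "g2"))
        assert dist[PERMS.index((0, 1, 2))] == 1.0
        assert dist.sum() == pytest.approx(1.0)

    def test_tied_sample_splits_mass(self):
        ds = make_dataset([[1.0], [1.0], [2.0]], class1_count=1)
        dist = ordering_distribution(ds, CLASS_1, ("g0", "g1", "g2"))
        assert dist[PERMS.index((0, 1, 2))] == 0.5
        assert dist[PERMS.index((1, 0, 2))] == 0.5

    def test_three_distinct_orderings(self):
        ds = cyclic_triple_dataset()
        dist = ordering_distribution(ds, CLASS_1, ("g0", "g1", "g2"))
        cyclic = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
        for p in PERMS:
            assert dist[PERMS.index(p)] == pytest.approx(1 / 3 if p in cyclic else 0.0)

    def test_duplicate_gene_rejected(self):
        ds = make_dataset([[1], [2], [3]], class1_count=1)
        with pytest.raises(DataError):
            ordering_distribution(ds, CLASS_1, ("g0", "g0", "g2"))


class TestTstScore:
    def test_identical_distributions(self):
        d = np.array([0.5, 0.5, 0, 0, 0, 0])
        assert tst_score(d, d) == 0.0

    def test_disjoint_supports(self):
        d1 = np.array([0.5, 0, 0, 0.25, 0.25, 0])
        d2 = np.array([0, 0.5, 0.25, 0, 0, 0.25])
        assert tst_score(d1, d2) == 1.0

    def test_partial_overlap(self):
        d1 = np.array([1.0, 0, 0, 0, 0, 0])
        d2 = np.array([0.5, 0.5, 0, 0, 0, 0])
        assert tst_score(d1, d2) == 0.5

    def test_zero_iff_equal_and_bounded(self):
        rng = np.random.default_rng(40)
        for _ in range(50):
            a = rng.dirichlet(np.ones(6))
            b = rng.dirichlet(np.ones(6))
            s = tst_score(a, b)
            assert 0.0 <= s <= 1.0
            assert (s == 0.0) == bool(np.allclose(a, b))


class TestTrainTst:
    def test_cyclic_planted_triple_wins_with_score_one(self):
        ds = cyclic_triple_dataset(extra_genes=5)
        model = train_tst(ds, {"filter_n": 0})
        assert model.triple == ("g0", "g1", "g2")
        assert model.score == 1.0
        # the same construction caps every embedded pairwise Delta at 1/3
        for gi, gj in (("g0", "g1"), ("g0", "g2"), ("g1", "g2")):
            assert pair_score(ds, gi, gj).delta == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        ds = random_dataset(4000 + seed, n_genes=6, n1=4, n2=4)
        model = train_tst(ds, {"filter_n": 0})
        triple, tv = brute_force_tst(ds)
        assert model.triple == triple
        assert model.score == pytest.approx(float(tv), abs=1e-12)

    def test_identical_classes_tie_to_first_triple(self):
        block = np.random.default_rng(41).normal(size=(5, 4))
        ds = make_dataset(np.hstack([block, block]), class1_count=4)
        model = train_tst(ds, {"filter_n": 0})
        assert model.score == 0.0
        assert model.triple == ("g0", "g1", "g2")

    def test_fewer_than_three_genes_rejected(self):
        ds = make_dataset([[1, 2, 3, 4], [4, 3, 2, 1]], class1_count=2)
        with pytest.raises(DataError):
            train_tst(ds, {"filter_n": 0})

    @pytest.mark.parametrize("seed", range(10))
    def test_pair_delta_bounded_by_triple_tv(self, seed):
        # projecting the 6-ordering distributions onto one pair can only
        # shrink the distance, so pair Delta <= triple TV
        ds = random_dataset(5000 + seed, n_genes=4, n1=5, n2=5)
        from relexp.tst import ordering_distribution as od

        for tri in [("g0", "g1", "g2"), ("g0", "g2", "g3"), ("g1", "g2", "g3")]:
            tv = tst_score(
                od(ds, CLASS_1, tri), od(ds, CLASS_2, tri)
            )
            for a in range(3):
                for b in range(a + 1, 3):
                    assert pair_score(ds, tri[a], tri[b]).delta <= tv + 1e-12


class TestClassifyTst:
    @pytest.fixture
    def model(self):
        return train_tst(cyclic_triple_dataset(), {"filter_n": 0})

    def test_permutation_seen_in_one_class(self, model):
        # ascending g0<g1<g2 is a cyclic (class 1) ordering
        assert classify_tst(model, {"g0": 1.0, "g1": 2.0, "g2": 3.0}) == CLASS_1
        # anti-cyclic ordering g0<g2<g1 belongs to class 2
        assert classify_tst(model, {"g0": 1.0, "g1": 3.0, "g2": 2.0}) == CLASS_2

    def test_unseen_permutation_falls_back_to_majority(self):
        # class 1 (3 samples) sees only one ordering; class 2 (2 samples) another
        ds = make_dataset(
            [[1, 1, 1, 3, 3], [2, 2, 2, 2, 2], [3, 3, 3, 1, 1]], class1_count=3
        )
        model = train_tst(ds, {"filter_n": 0})
        # ordering g1<g0<g2 was never observed: majority class (1) wins
        assert classify_tst(model, {"g0": 2.0, "g1": 1.0, "g2": 3.0}) == CLASS_1

    def test_tied_values_resolved_by_gene_order(self):
        assert sample_permutation([1.0, 1.0, 2.0]) == PERMS.index((0, 1, 2))
        assert sample_permutation([2.0, 1.0, 1.0]) == PERMS.index((1, 2, 0))

    def test_missing_gene_rejected(self, model):
        with pytest.raises(KeyError):
            classify_tst(model, {"g0": 1.0, "g1": 2.0})
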