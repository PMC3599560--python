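import numpy as np
import pytest

from relexp.datamodel import CLASS_1, CLASS_2, DataError
from relexp.dirac import (
    classify_dirac,
    network_classification_rate,
    rank_conservation_index,
    rank_matching_score,
    rank_template,
    train_dirac,
)
from relexp.io_formats import GeneSet, GeneSetCollection
from relexp.tsp import classify_tsp, train_tsp

from conftest import make_dataset, random_dataset


def reversing_network_dataset(n_noise=6, m=8, seed=0):
    """g0>g1>g2 ladder in class 1, reversed in class 2, plus noise genes."""
    rng = np.random.default_rng(seed)
    values = rng.normal(loc=5.0, size=(3 + n_noise, 2 * m))
    for pos, gene in enumerate((0, 1, 2)):
        values[gene, :m] = 20.0 - 6.0 * pos
        values[gene, m:] = 8.0 + 6.0 * pos
    return make_dataset(values, class1_count=m)


class TestRankTemplate:
    def test_consistent_ranking(self):
        ds = make_dataset([[3, 3], [2, 2], [1, 1]], class1_count=2)
        t = rank_template(ds, CLASS_1, ["g0", "g1", "g2"])
        assert t.pair_list == [("g0", "g1"), ("g0", "g2"), ("g1", "g2")]
        assert t.bits == [1, 1, 1]

    def test_exact_split_gives_bit_zero(self):
        ds = make_dataset([[2, 2, 0, 0], [1, 1, 1, 1]], class1_count=4)
        t = rank_template(ds, CLASS_1, ["g0", "g1"])
        assert t.bits == [0]

    def test_single_sample_class(self):
        ds = make_dataset([[1, 9], [2, 8]], labels={"s0": 1, "s1": 2})
        t = rank_template(ds, CLASS_1, ["g0", "g1"])
        assert t.bits == [0]  # sample s0 has g0 < g1

    def test_too_few_present_genes_rejected(self):
        ds = make_dataset([[1, 2]], class1_count=1)
        with pytest.raises(DataError):
            rank_template(ds, CLASS_1, ["g0", "ghost"])


class TestRankMatchingScore:
    @pytest.fixture
    def template(self):
        ds = make_dataset([[3, 3], [2, 2], [1, 1]], class1_count=2)
        return rank_template(ds, CLASS_1, ["g0", "g1", "g2"])

    def test_exact_match(self, template):
        assert rank_matching_score({"g0": 3, "g1": 2, "g2": 1}, template) == 1.0

    def test_full_reversal(self, template):
        assert rank_matching_score({"g0": 1, "g1": 2, "g2": 3}, template) == 0.0

    def test_one_mismatched_pair(self, template):
        # g1 > g0 flips one of the three pairs
        assert rank_matching_score({"g0": 2.5, "g1": 3, "g2": 1}, template) == pytest.approx(2 / 3)

    def test_tie_matches_neither(self, template):
        assert rank_matching_score({"g0": 3, "g1": 3, "g2": 1}, template) == pytest.approx(2 / 3)


class TestConservationIndex:
    def test_identically_ordered_class(self):
        ds = make_dataset([[3, 3, 3], [2, 2, 2], [1, 1, 1]], class1_count=3)
        assert rank_conservation_index(ds, CLASS_1, ["g0", "g1", "g2"]) == 1.0

    def test_two_opposite_samples(self):
        ds = make_dataset([[1, 3], [2, 2.5], [3, 1]], class1_count=2)
        # each sample matches the tie-resolved majority template on half
        assert rank_conservation_index(ds, CLASS_1, ["g0", "g1", "g2"]) == 0.5

    def test_shuffled_orderings_stay_above_half(self):
        rng = np.random.default_rng(60)
        values = rng.normal(size=(6, 40))
        ds = make_dataset(values, class1_count=40)
        r = rank_conservation_index(ds, CLASS_1, list(ds.gene_ids))
        assert r >= 0.5 - 0.05

    def test_above_label_permutation_baseline_on_planted_signal(self):
        ds = reversing_network_dataset()
        genes = ["g0", "g1", "g2"]
        observed = rank_conservation_index(ds, CLASS_1, genes)
        rng = np.random.default_rng(61)
        ids = list(ds.sample_ids)
        baseline = []
        for _ in range(100):
            perm = rng.permutation(len(ids))
            labels = {ids[p]: ds.class_of[ids[j]] for j, p in enumerate(perm)}
            baseline.append(rank_conservation_index(ds.with_classes(labels), CLASS_1, genes))
        assert observed >= np.mean(baseline)


class TestClassificationRate:
    def test_perfectly_reversing_network(self):
        ds = reversing_network_dataset()
        assert network_classification_rate(ds, ["g0", "g1", "g2"]) == 1.0

    def test_null_network_near_chance(self):
        ds = random_dataset(62, n_genes=8, n1=20, n2=20)
        rate = network_classification_rate(ds, list(ds.gene_ids))
        assert abs(rate - 0.5) <= 0.25  # resubstitution optimism allowed

    def test_single_pair_network(self):
        ds = make_dataset([[2, 2, 1, 1], [1, 1, 2, 2]], class1_count=2)
        assert network_classification_rate(ds, ["g0", "g1"]) == 1.0


class TestTrainDirac:
    def _collection(self, ds, planted_genes):
        rng = np.random.default_rng(63)
        sets = [GeneSet("PLANTED", "signal", planted_genes)]
        noise_pool = [g for g in ds.gene_ids if g not in planted_genes]
        for i in range(9):
            pick = rng.choice(noise_pool, size=3, replace=False)
            sets.append(GeneSet(f"NOISE_{i}", "decoy", list(pick)))
        return GeneSetCollection(sets)

    def test_planted_network_selected(self):
        ds = reversing_network_dataset()
        coll = self._collection(ds, ["g0", "g1", "g2"])
        model = train_dirac(ds, coll, {"min_size": 3, "m": 1})
        assert model.networks[0].name == "PLANTED"
        assert model.networks[0].classification_rate == 1.0

    def test_m_larger_than_eligible_keeps_all(self):
        ds = reversing_network_dataset()
        coll = GeneSetCollection([GeneSet("ONLY", "x", ["g0", "g1", "g2"])])
        model = train_dirac(ds, coll, {"min_size": 3, "m": 5})
        assert model.m == 1

    def test_min_size_excluding_everything_rejected(self):
        ds = reversing_network_dataset()
        coll = GeneSetCollection([GeneSet("SMALL", "x", ["g0", "g1"])])
        with pytest.raises(DataError, match="3"):
            train_dirac(ds, coll, {"min_size": 3, "m": 1})

    def test_networks_intersected_with_dataset_before_size_test(self):
        ds = reversing_network_dataset()
        coll = GeneSetCollection(
            [GeneSet("PARTIAL", "x", ["g0", "g1", "g2", "NOT_MEASURED_1", "NOT_MEASURED_2"])]
        )
        model = train_dirac(ds, coll, {"min_size": 3, "m": 1})
        assert model.networks[0].genes == ["g0", "g1", "g2"]


class TestClassifyDirac:
    def test_single_network_decision(self):
        ds = reversing_network_dataset()
        coll = GeneSetCollection([GeneSet("NET", "x", ["g0", "g1", "g2"])])
        model = train_dirac(ds, coll, {"min_size": 3, "m": 1})
        assert classify_dirac(model, {"g0": 3.0, "g1": 2.0, "g2": 1.0}) == CLASS_1
        assert classify_dirac(model, {"g0": 1.0, "g1": 2.0, "g2": 3.0}) == CLASS_2

    def test_majority_of_network_votes(self):
        ds = reversing_network_dataset()
        coll = GeneSetCollection(
            [
                GeneSet("A", "x", ["g0", "g1"]),
                GeneSet("B", "x", ["g0", "g2"]),
                GeneSet("C", "x", ["g1", "g2"]),
            ]
        )
        model = train_dirac(ds, coll, {"min_size": 2, "m": 3})
        # sample agreeing with class 1 on two of three networks
        vec = {"g0": 3.0, "g1": 2.0, "g2": 2.5}
        assert classify_dirac(model, vec) == CLASS_1

    def test_all_networks_tied_falls_back_to_majority_class(self):
        ds = reversing_network_dataset(m=8)
        # drop one class-2 sample so class 1 is the majority
        ids = ds.sample_ids[:-1]
        ds = ds.subset_samples(ids)
        coll = GeneSetCollection([GeneSet("NET", "x", ["g0", "g1", "g2"])])
        model = train_dirac(ds, coll, {"min_size": 3, "m": 1})
        tied = {"g0": 1.0, "g1": 1.0, "g2": 1.0}
        assert classify_dirac(model, tied) == CLASS_1


class TestCrossChecks:
    def test_monotone_transform_invariance(self):
        ds = random_dataset(64, n_genes=6, n1=6, n2=6)
        genes = list(ds.gene_ids)
        t = rank_template(ds, CLASS_1, genes)
        warped = make_dataset(np.exp(ds.values / 3.0), labels=ds.class_of)
        t2 = rank_template(warped, CLASS_1, genes)
        assert t.bits == t2.bits
        assert network_classification_rate(ds, genes) == network_classification_rate(
            warped, genes
        )

    def test_two_gene_reversing_network_agrees_with_tsp(self):
        # on pairs whose majority orientation actually flips between the
        # classes, the one-network DIRAC decision is the TSP reversal rule
        from relexp.tsp import order_probability

        checked = 0
        for seed in range(30):
            ds = random_dataset(7000 + seed, n_genes=2, n1=6, n2=6)
            p1 = order_probability(ds, CLASS_1, "g0", "g1")
            p2 = order_probability(ds, CLASS_2, "g0", "g1")
            if not ((p1 - 0.5) * (p2 - 0.5) < 0):
                continue  # no majority reversal: rules differ legitimately
            coll = GeneSetCollection([GeneSet("PAIR", "x", ["g0", "g1"])])
            dirac_model = train_dirac(ds, coll, {"min_size": 2, "m": 1})
            tsp_model = train_tsp(ds)
            for sid in ds.sample_ids:
                vec = ds.sample_vector(sid)
                if vec["g0"] == vec["g1"]:
                    continue
                assert classify_dirac(dirac_model, vec) == classify_tsp(tsp_model, vec)
            checked += 1
        assert checked >= 5
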