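import numpy as np
import pytest

from relexp.datamodel import CLASS_1, CLASS_2, DataError
from relexp.evaluation import cross_validate
from relexp.io_formats import (
    assign_classes_by_cohort,
    read_csv_expression,
    read_gmt,
    read_soft,
)
from relexp.learners import get_learner
from relexp.synthetic import (
    NetworkRerank,
    PairReversal,
    SyntheticSpec,
    TripleCycle,
    default_fixture_spec,
    generate,
    write_fixture_suite,
)
from relexp.tsp import pair_score, train_tsp
from relexp.tst import train_tst
from relexp.dirac import train_dirac


class TestGenerate:
    def test_deterministic_given_seed(self):
        spec = default_fixture_spec(seed=4)
        a, _ = generate(spec)
        b, _ = generate(spec)
        assert a == b

    def test_different_seed_changes_values(self):
        a, _ = generate(default_fixture_spec(seed=1))
        b, _ = generate(default_fixture_spec(seed=2))
        assert not np.array_equal(a.values, b.values)

    def test_dataset_invariants(self):
        ds, gene_sets = generate(default_fixture_spec())
        assert ds.n_genes == 30 and ds.n_samples == 40
        assert len(ds.class_sample_ids(CLASS_1)) == 20
        assert len(ds.class_sample_ids(CLASS_2)) == 20
        for gs in gene_sets:
            assert gs.gene_ids and len(set(gs.gene_ids)) == len(gs.gene_ids)

    def test_planted_pair_orders_reverse(self):
        spec = SyntheticSpec(
            n_genes=10, n_samples_per_class=25, planted=(PairReversal(0, 1, gap=8.0),), seed=3
        )
        ds, _ = generate(spec)
        s = pair_score(ds, "G0001", "G0002")
        assert s.delta == 1.0

    def test_null_spec_gives_near_zero_cv(self):
        # labels carry no information: expected CV MCC is 0, so the mean
        # over independently drawn null datasets must sit near 0 even
        # though any single dataset's best pair can correlate by chance
        means = []
        for seed in range(5):
            ds, _ = generate(SyntheticSpec(n_genes=15, n_samples_per_class=20, seed=seed))
            result = cross_validate(ds, get_learner("tsp"), {}, k=10, repeats=2, seed=seed)
            means.append(result.mean_mcc)
        assert abs(np.mean(means)) < 0.3

    def test_overlapping_signals_rejected(self):
        spec = SyntheticSpec(
            n_genes=10,
            planted=(PairReversal(0, 1), TripleCycle(1, 2, 3)),
        )
        with pytest.raises(DataError, match="contradictory|planted twice"):
            generate(spec)

    def test_out_of_range_signal_rejected(self):
        with pytest.raises(DataError):
            generate(SyntheticSpec(n_genes=5, planted=(PairReversal(0, 7),)))

    def test_halving_gap_does_not_increase_mean_delta(self):
        # planted effect sizes scale monotonically (averaged over seeds)
        def mean_delta(gap):
            deltas = []
            for seed in range(20):
                spec = SyntheticSpec(
                    n_genes=8,
                    n_samples_per_class=8,
                    planted=(PairReversal(0, 1, gap=gap),),
                    seed=100 + seed,
                )
                ds, _ = generate(spec)
                deltas.append(pair_score(ds, "G0001", "G0002").delta)
            return np.mean(deltas)

        assert mean_delta(0.5) >= mean_delta(0.25)

    def test_lognormal_option_preserves_ranks(self):
        base = SyntheticSpec(n_genes=8, n_samples_per_class=6, seed=5)
        warped = SyntheticSpec(n_genes=8, n_samples_per_class=6, seed=5, lognormal=True)
        a, _ = generate(base)
        b, _ = generate(warped)
        for sid in a.sample_ids:
            assert list(np.argsort(a.column(sid))) == list(np.argsort(b.column(sid)))


@pytest.fixture(scope="module")
def suite(tmp_path_factory):
    directory = tmp_path_factory.mktemp("suite")
    manifest = write_fixture_suite(directory)
    return directory, manifest


class TestFixtureSuite:
    def test_round_trips_through_readers(self, suite):
        directory, manifest = suite
        ds, _ = generate(default_fixture_spec())
        csv_ds = read_csv_expression(directory / "expression.csv")
        assert csv_ds.gene_ids == ds.gene_ids
        np.testing.assert_array_equal(csv_ds.values, ds.values)
        soft_ds, cohorts = read_soft(directory / "expression.soft")
        np.testing.assert_array_equal(soft_ds.values, ds.values)
        assert set(cohorts.tags()) == {"normal", "cancer"}

    def test_cohorts_assign_planted_classes(self, suite):
        directory, manifest = suite
        soft_ds, cohorts = read_soft(directory / "expression.soft")
        labeled = assign_classes_by_cohort(soft_ds, cohorts, ["normal"], ["cancer"])
        ds, _ = generate(default_fixture_spec())
        assert labeled.class_of == ds.class_of

    def test_planted_signals_recovered(self, suite):
        directory, manifest = suite
        soft_ds, cohorts = read_soft(directory / "expression.soft")
        ds = assign_classes_by_cohort(soft_ds, cohorts, ["normal"], ["cancer"])
        gene_sets = read_gmt(directory / "networks.gmt")

        planted_genes = {g for sig in manifest["planted"] for g in sig["genes"]}
        tsp_model = train_tsp(ds)
        assert tsp_model.pair.delta == 1.0
        assert {tsp_model.pair.gene_i, tsp_model.pair.gene_j} <= planted_genes

        tst_model = train_tst(ds, {"filter_n": 0})
        assert tst_model.score == 1.0
        assert set(tst_model.triple) <= planted_genes

        planted_net = next(
            s["network"] for s in manifest["planted"] if s["kind"] == "network_rerank"
        )
        dirac_model = train_dirac(ds, gene_sets, {"min_size": 3, "m": 1})
        assert dirac_model.networks[0].name == planted_net
        assert dirac_model.networks[0].classification_rate == 1.0
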