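"""Handoff, uncertainty queries, oracle ledger, and the AL loop."""

import numpy as np
import pytest

from ssmirna.active_learning import (
    OracleLedger,
    SimulatedOracle,
    form_al_seed,
    query_uncertain,
    run_active_learning,
)
from ssmirna.core import ExperimentConfig, LabeledPool, UnlabeledPool
from ssmirna.cotraining import CoTrainingResult, ViewState, run_mvct
from ssmirna.pipeline import holdout_split


@pytest.fixture(scope="module")
def mvct_result(small_dataset):
    train, hold = holdout_split(small_dataset, 0.2, np.random.default_rng(2))
    config = ExperimentConfig(n_trees=25)
    return train, hold, run_mvct(train, config, np.random.default_rng(3), holdout=hold)


class TestFormAlSeed:
    def test_union_size_is_54_minus_cross_view_duplicates(self, mvct_result):
        # each view ends at 32; the union collapses the 10 shared seed
        # entries plus any ids that collided into both views' pools
        _, _, result = mvct_result
        labeled, unlabeled, conflicts = form_al_seed(result)
        names = result.view_names
        duplicates = set(result.views[names[0]].labeled.ids) & set(
            result.views[names[1]].labeled.ids
        )
        assert len(duplicates) >= 10  # at least the seed
        assert len(labeled) == 64 - len(duplicates)
        if not result.collisions:
            assert len(labeled) == 54  # 10 seed + 22 + 22

    def test_unlabeled_is_pool_intersection_disjoint_from_labeled(self, mvct_result):
        train, _, result = mvct_result
        labeled, unlabeled, _ = form_al_seed(result)
        names = result.view_names
        expected = set(result.views[names[0]].unlabeled.ids) & set(
            result.views[names[1]].unlabeled.ids
        )
        assert set(unlabeled.ids) == expected
        assert not set(unlabeled.ids) & set(labeled.ids)

    def test_constructed_collision_collapses_to_53(self):
        # both views pseudo-labeled sample x: the union keeps one entry
        def view(name, extra_label, extra_conf):
            pool = LabeledPool()
            for k in range(5):
                pool.add(f"p{k}", 1, source="seed")
                pool.add(f"n{k}", 0, source="seed")
            for k in range(21):
                pool.add(f"{name}_{k}", k % 2, source="cotrain_pseudo", confidence=0.9)
            pool.add("x", extra_label, source="cotrain_pseudo", confidence=extra_conf)
            return ViewState(name=name, labeled=pool, unlabeled=UnlabeledPool(["u1", "u2"]))

        result = CoTrainingResult(
            views={"a": view("a", 1, 0.95), "b": view("b", 0, 0.7)},
            records=[],
        )
        labeled, _, conflicts = form_al_seed(result)
        assert len(labeled) == 53
        assert len(conflicts) == 1
        assert labeled.label_of("x") == 1  # higher confidence wins

    def test_zero_iteration_handoff_is_just_the_seed(self, small_dataset):
        train, hold = holdout_split(small_dataset, 0.2, np.random.default_rng(2))
        config = ExperimentConfig(n_trees=25, mvct_iterations=0)
        result = run_mvct(train, config, np.random.default_rng(3), holdout=hold)
        labeled, unlabeled, _ = form_al_seed(result)
        assert len(labeled) == 10
        assert len(unlabeled) == len(train) - 10


class TestQueryUncertain:
    def test_least_confident_each_side(self):
        pos, neg = query_uncertain({"a": 0.51, "b": 0.95, "c": 0.45, "d": 0.05})
        assert (pos, neg) == ("a", "c")

    def test_fallback_when_no_predicted_negatives(self):
        pos, neg = query_uncertain({"a": 0.9, "b": 0.8})
        assert (pos, neg) == ("b", "a")  # the two closest to the boundary

    def test_singleton_pool(self):
        assert query_uncertain({"z": 0.7}) == ("z", None)
        assert query_uncertain({"z": 0.2}) == (None, "z")

    def test_tie_breaks_lexicographically(self):
        pos, neg = query_uncertain({"b": 0.6, "a": 0.6, "c": 0.4, "d": 0.4})
        assert (pos, neg) == ("a", "c")


class TestOracle:
    def test_reveals_truth_and_increments_ledger(self, small_dataset):
        oracle = SimulatedOracle(small_dataset)
        sample = small_dataset.ids[0]
        truth = oracle.label(sample, iteration=1)
        assert truth == small_dataset.true_label(sample)
        assert oracle.ledger.total == 1

    def test_requery_rejected(self, small_dataset):
        oracle = SimulatedOracle(small_dataset)
        sample = small_dataset.ids[0]
        oracle.label(sample)
        with pytest.raises(ValueError, match="already labeled"):
            oracle.label(sample)

    def test_unknown_truth_rejected(self, small_dataset):
        import pandas as pd

        labels = small_dataset.labels.copy()
        labels.iloc[0] = pd.NA
        from ssmirna.core import Dataset

        masked = Dataset(small_dataset.views, labels)
        oracle = SimulatedOracle(masked)
        with pytest.raises(ValueError, match="no withheld ground truth"):
            oracle.label(masked.ids[0])


class TestRunActiveLearning:
    def test_default_run_budget_and_growth(self, mvct_result):
        train, hold, result = mvct_result
        labeled, unlabeled, _ = form_al_seed(result)
        config = ExperimentConfig(n_trees=25)
        al = run_active_learning(
            train, labeled, unlabeled, config, np.random.default_rng(5), holdout=hold
        )
        assert len(al.records) == 12  # initial + 11 iterations
        assert al.ledger.total == 22  # 2 oracle labels per iteration
        assert len(al.labeled) <= len(labeled) + 22
        assert all(e["label"] is not None for e in al.ledger.entries)

    def test_no_id_queried_twice(self, mvct_result):
        train, hold, result = mvct_result
        labeled, unlabeled, _ = form_al_seed(result)
        config = ExperimentConfig(n_trees=25)
        al = run_active_learning(
            train, labeled, unlabeled, config, np.random.default_rng(5), holdout=hold
        )
        queried = al.ledger.queried_ids
        assert len(queried) == len(set(queried))

    def test_zero_iterations_gives_initial_classifier_only(self, mvct_result):
        train, hold, result = mvct_result
        labeled, unlabeled, _ = form_al_seed(result)
        config = ExperimentConfig(n_trees=25, al_iterations=0)
        al = run_active_learning(
            train, labeled, unlabeled, config, np.random.default_rng(5), holdout=hold
        )
        assert len(al.records) == 1
        assert al.ledger.total == 0

    def test_exhausted_pool_stops_early_without_error(self, mvct_result):
        train, hold, result = mvct_result
        labeled, _, _ = form_al_seed(result)
        tiny = UnlabeledPool(list(result.views[result.view_names[0]].unlabeled)[:3])
        config = ExperimentConfig(n_trees=25)
        al = run_active_learning(
            train, labeled, tiny, config, np.random.default_rng(5), holdout=hold
        )
        assert al.terminated_early
        assert al.ledger.total == 3
        assert len(al.unlabeled) == 0

    def test_oracle_truth_overwrites_pseudo_label(self, small_dataset):
        sample = small_dataset.ids[0]
        wrong = 1 - small_dataset.true_label(sample)
        pool = LabeledPool()
        pool.add(sample, wrong, source="cotrain_pseudo", confidence=0.6)
        oracle = SimulatedOracle(small_dataset)
        truth = oracle.label(sample)
        pool.replace(sample, truth, source="oracle")
        assert pool.entry(sample).source == "oracle"
        assert pool.label_of(sample) == truth


def test_ledger_rejects_duplicate_entries():
    ledger = OracleLedger()
    ledger.record("x", 1, 0)
    with pytest.raises(ValueError, match="already labeled"):
        ledger.record("x", 1, 1)
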