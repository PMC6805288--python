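"""Seed draw, confident-pair selection, and the co-training loop."""

import numpy as np
import pytest

from ssmirna.core import ExperimentConfig
from ssmirna.cotraining import draw_seed, run_mvct, select_confident
from ssmirna.pipeline import holdout_split


class TestDrawSeed:
    def test_default_seed_is_five_plus_five_shared_across_views(self, small_dataset, fast_config):
        views = draw_seed(small_dataset, fast_config, np.random.default_rng(1))
        names = list(views)
        assert len(names) == 2
        for state in views.values():
            assert len(state.labeled) == 10
            assert state.labeled.n_positive == 5 and state.labeled.n_negative == 5
        assert views[names[0]].labeled.ids == views[names[1]].labeled.ids

    def test_non_seed_samples_fill_both_unlabeled_pools(self, small_dataset, fast_config):
        views = draw_seed(small_dataset, fast_config, np.random.default_rng(1))
        for state in views.values():
            assert len(state.unlabeled) == len(small_dataset) - 10
            state.check_disjoint()

    def test_insufficient_class_counts_reported(self, small_dataset):
        config = ExperimentConfig(seed_pos=10_000)
        with pytest.raises(ValueError, match="need 10000"):
            draw_seed(small_dataset, config, np.random.default_rng(0))

    def test_zero_seed_pos_rejected(self, small_dataset):
        config = ExperimentConfig(seed_pos=0)
        with pytest.raises(ValueError):
            draw_seed(small_dataset, config, np.random.default_rng(0))

    def test_same_rng_seed_gives_identical_membership(self, small_dataset, fast_config):
        first = draw_seed(small_dataset, fast_config, np.random.default_rng(5))
        second = draw_seed(small_dataset, fast_config, np.random.default_rng(5))
        for name in first:
            assert first[name].labeled.ids == second[name].labeled.ids


class TestSelectConfident:
    def test_argmax_and_argmin(self):
        pos, neg = select_confident({"a": 0.51, "b": 0.95, "c": 0.45, "d": 0.05})
        assert (pos, neg) == ("b", "d")

    def test_all_equal_scores_fall_back_to_id_order(self):
        pos, neg = select_confident({"c": 0.5, "a": 0.5, "b": 0.5})
        assert (pos, neg) == ("a", "b")

    def test_singleton_pool_yields_one_side(self):
        assert select_confident({"x": 0.9}) == ("x", None)
        assert select_confident({"x": 0.2}) == (None, "x")

    def test_empty_pool_yields_nothing(self):
        assert select_confident({}) == (None, None)

    def test_returned_ids_are_distinct(self):
        pos, neg = select_confident({"a": 0.7, "b": 0.7})
        assert pos != neg


class TestRunMvct:
    @pytest.fixture(scope="class")
    def split(self, small_dataset):
        return holdout_split(small_dataset, 0.2, np.random.default_rng(2))

    def test_default_growth_trajectory_reaches_32(self, split, fast_config):
        train, hold = split
        result = run_mvct(train, fast_config, np.random.default_rng(3), holdout=hold)
        sizes = {
            view: [r.n_labeled[view] for r in result.records] for view in result.view_names
        }
        for trajectory in sizes.values():
            assert trajectory == list(range(10, 33, 2))
        for state in result.views.values():
            assert len(state.labeled) == 32
            state.check_disjoint()

    def test_zero_iterations_returns_seed_state(self, split, fast_config):
        train, hold = split
        config = ExperimentConfig(n_trees=25, mvct_iterations=0)
        result = run_mvct(train, config, np.random.default_rng(3), holdout=hold)
        assert len(result.records) == 1
        assert all(len(s.labeled) == 10 for s in result.views.values())

    def test_no_oracle_cost_all_additions_are_pseudo_labels(self, split, fast_config):
        train, hold = split
        result = run_mvct(train, fast_config, np.random.default_rng(3), holdout=hold)
        for state in result.views.values():
            sources = {state.labeled.entry(i).source for i in state.labeled.ids}
            assert sources == {"seed", "cotrain_pseudo"}
            n_pseudo = sum(
                1 for i in state.labeled.ids if state.labeled.entry(i).source == "cotrain_pseudo"
            )
            assert n_pseudo == 22

    def test_selected_ids_leave_both_unlabeled_pools(self, split, fast_config):
        train, hold = split
        result = run_mvct(train, fast_config, np.random.default_rng(3), holdout=hold)
        names = result.view_names
        added = set()
        for record in result.records[1:]:
            for view in names:
                added.update(record.added[view]["positive"])
                added.update(record.added[view]["negative"])
        for view in names:
            assert not added & set(result.views[view].unlabeled.ids)

    def test_identical_views_and_rng_collide_but_pools_stay_valid(self, fast_config):
        # same feature columns in both views: selections coincide each
        # iteration, exercising the collision rule
        import pandas as pd

        rng = np.random.default_rng(4)
        n = 80
        ids = [f"s{i:03d}" for i in range(n)]
        y = np.array([1] * 20 + [0] * 60)
        X = rng.standard_normal((n, 4)) + np.outer(y, [2, 2, 0, 0])
        views = {
            "a": pd.DataFrame(X, index=ids, columns=[f"a{j}" for j in range(4)]),
            "b": pd.DataFrame(X.copy(), index=ids, columns=[f"b{j}" for j in range(4)]),
        }
        labels = pd.Series(y, index=ids, dtype="Int64")
        from ssmirna.core import Dataset

        dataset = Dataset(views, labels)
        config = ExperimentConfig(n_trees=25, mvct_iterations=5)
        result = run_mvct(dataset, config, np.random.default_rng(6))
        assert result.collisions  # identical views must collide
        for state in result.views.values():
            state.check_disjoint()
            state.labeled.require_both_classes()
        # both views hold the same ids (every addition was a collision)
        names = result.view_names
        assert set(result.views[names[0]].labeled.ids) == set(result.views[names[1]].labeled.ids)

    def test_pseudo_labels_mostly_correct_when_classes_separate(self, small_dataset, fast_config):
        train, hold = holdout_split(small_dataset, 0.2, np.random.default_rng(2))
        result = run_mvct(train, fast_config, np.random.default_rng(7), holdout=hold)
        assert result.pseudo_label_fidelity() >= 0.8
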