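"""Stage 1 — multi-view co-training (MVCT) with per-view labeled pools.

Classical co-training maintains one shared labeled pool; the variant
implemented here instead keeps two independent labeled pools, one per
view, and cross-feeds: at each iteration, the sample each view most
confidently predicts positive and negative is added to the *alternate*
view's labeled pool with its predicted (pseudo) label. Keeping the
pools disjoint beyond the shared seed slows convergence between the
views, which would otherwise plateau the co-training benefit.

No oracle labels are consumed in this stage: every addition is a
pseudo-label. With defaults (5+/5- seed, 11 iterations, 1 positive +
1 negative per view per iteration), each view's labeled pool ends at
10 + 22 = 32 working labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    NEGATIVE,
    POSITIVE,
    ClassifierHandle,
    Dataset,
    ExperimentConfig,
    LabeledPool,
    UnlabeledPool,
    derive_seed,
)
from .evaluation import auprc

log = logging.getLogger(__name__)

__all__ = ["ViewState", "CoTrainingResult", "draw_seed", "select_confident", "run_mvct"]


@dataclass
class ViewState:
    """One co-training view: its pools and fitted classifier."""

    name: str
    labeled: LabeledPool
    unlabeled: UnlabeledPool
    classifier: ClassifierHandle | None = None

    def check_disjoint(self) -> None:
        clash = [i for i in self.unlabeled if i in self.labeled]
        if clash:
            raise AssertionError(
                f"view {self.name!r}: ids in both pools: {clash[:5]}"
            )


@dataclass
class IterationRecord:
    """Bookkeeping for one MVCT iteration (or the seed state, iteration 0)."""

    iteration: int
    added: dict[str, dict[str, list[str]]]  # view -> {"positive": ids, "negative": ids}
    holdout_auprc: dict[str, float]  # view -> AUPRC on the frozen holdout
    n_labeled: dict[str, int]
    n_unlabeled: dict[str, int]
    pseudo_label_correct: int = 0
    pseudo_label_total: int = 0


@dataclass
class CoTrainingResult:
    """Final view states plus the per-iteration audit trail."""

    views: dict[str, ViewState]
    records: list[IterationRecord]
    collisions: list[dict] = field(default_factory=list)
    terminated_early: bool = False

    @property
    def view_names(self) -> list[str]:
        return list(self.views)

    def curve(self, view: str) -> list[tuple[int, float]]:
        return [(r.iteration, r.holdout_auprc[view]) for r in self.records]

    def pseudo_label_fidelity(self) -> float:
        """Fraction of pseudo-labels matching withheld truth (NaN if none)."""
        total = sum(r.pseudo_label_total for r in self.records)
        if total == 0:
            return float("nan")
        return sum(r.pseudo_label_correct for r in self.records) / total


def draw_seed(
    dataset: Dataset,
    config: ExperimentConfig,
    rng: np.random.Generator,
    view_names: list[str] | None = None,
) -> dict[str, ViewState]:
    """Draw the shared seed pool and initialize both views' pools.

    Samples ``seed_pos`` positives and ``seed_neg`` negatives uniformly
    from the training samples with known ground truth; both views start
    from this identical seed (counted against the oracle budget), and
    every other training sample enters both views' unlabeled pools.
    """
    config.validate()
    if view_names is None:
        view_names = dataset.view_names
    if len(view_names) < 2:
        raise ValueError("co-training needs two views")

    positives = [i for i in dataset.labeled_ids() if dataset.true_label(i) == POSITIVE]
    negatives = [i for i in dataset.labeled_ids() if dataset.true_label(i) == NEGATIVE]
    if len(positives) < config.seed_pos or len(negatives) < config.seed_neg:
        raise ValueError(
            f"insufficient labeled samples for seed draw: need "
            f"{config.seed_pos}+/{config.seed_neg}-, have "
            f"{len(positives)}+/{len(negatives)}-"
        )
    seed_pos = [positives[k] for k in rng.choice(len(positives), config.seed_pos, replace=False)]
    seed_neg = [negatives[k] for k in rng.choice(len(negatives), config.seed_neg, replace=False)]
    seed_ids = set(seed_pos) | set(seed_neg)

    views: dict[str, ViewState] = {}
    for name in view_names:
        pool = LabeledPool()
        for i in seed_pos:
            pool.add(i, POSITIVE, source="seed")
        for i in seed_neg:
            pool.add(i, NEGATIVE, source="seed")
        unlabeled = UnlabeledPool(i for i in dataset.ids if i not in seed_ids)
        views[name] = ViewState(name=name, labeled=pool, unlabeled=unlabeled)
    return views


def select_confident(scores: dict[str, float]) -> tuple[str | None, str | None]:
    """Most confident positive (argmax) and negative (argmin) of a score map.

    Ties are broken by lexicographically smallest id; the two returned
    ids are distinct. A singleton pool yields a single id on the side
    its score favours, the other side ``None``. An empty map returns
    ``(None, None)`` (the caller terminates the stage).
    """
    if not scores:
        return None, None
    ids = sorted(scores)
    if len(ids) == 1:
        only = ids[0]
        if scores[only] >= 0.5:
            return only, None
        return None, only
    top = max(scores[i] for i in ids)
    pos = min(i for i in ids if scores[i] == top)
    rest = [i for i in ids if i != pos]
    bottom = min(scores[i] for i in rest)
    neg = min(i for i in rest if scores[i] == bottom)
    return pos, neg


def _holdout_scorer(holdout: Dataset | None):
    """AUPRC of a fitted view classifier on the frozen holdout (NaN if none)."""

    def score(handle: ClassifierHandle) -> float:
        if holdout is None or len(holdout) == 0:
            return float("nan")
        ids = holdout.ids
        labels = [holdout.true_label(i) for i in ids]
        return auprc(handle.score(ids, holdout), labels)

    return score


def run_mvct(
    dataset: Dataset,
    config: ExperimentConfig,
    rng: np.random.Generator,
    holdout: Dataset | None = None,
    views: dict[str, ViewState] | None = None,
) -> CoTrainingResult:
    """Run the co-training stage on the training partition.

    ``dataset`` is the training partition (seed + unlabeled pool);
    ``holdout`` is the frozen test partition used only for learning-curve
    AUPRC. If ``views`` is None the seed is drawn here with ``rng``.

    Per iteration: both views are refit on their current labeled pools;
    each view picks its most confident positive and negative from its
    own unlabeled pool; each pick joins the alternate view's labeled
    pool with the predicted label and leaves *both* views' unlabeled
    pools (preventing conflicting pseudo-labels later and keeping the
    stage-2 pool intersection well defined). If both views pick the same
    sample with conflicting labels, the higher-confidence prediction
    wins for both pools and the collision is logged.

    Record 0 of the result is the seed state; records 1..n the
    iterations. Exhausted unlabeled pools end the stage early with a
    logged notice, never an error.
    """
    config.validate()
    if views is None:
        views = draw_seed(dataset, config, rng)
    names = list(views)
    if len(names) != 2:
        raise ValueError(f"exactly two views required, got {names}")
    alternate = {names[0]: names[1], names[1]: names[0]}

    repetition_seed = derive_seed(rng)

    def fit_all() -> None:
        for name in names:
            seed = (
                repetition_seed
                if config.classifier_reseed == "per_repetition"
                else derive_seed(rng)
            )
            handle = ClassifierHandle(name, n_trees=config.n_trees, random_state=seed)
            views[name].classifier = handle.fit(views[name].labeled, dataset)

    holdout_auprc = _holdout_scorer(holdout)

    def snapshot(iteration: int, added, correct: int, total: int) -> IterationRecord:
        return IterationRecord(
            iteration=iteration,
            added=added,
            holdout_auprc={n: holdout_auprc(views[n].classifier) for n in names},
            n_labeled={n: len(views[n].labeled) for n in names},
            n_unlabeled={n: len(views[n].unlabeled) for n in names},
            pseudo_label_correct=correct,
            pseudo_label_total=total,
        )

    fit_all()
    records = [snapshot(0, {n: {"positive": [], "negative": []} for n in names}, 0, 0)]
    collisions: list[dict] = []
    terminated_early = False

    for iteration in range(1, config.mvct_iterations + 1):
        # each view scores its own unlabeled pool and nominates a pair
        picks: dict[str, list[tuple[str, int, float]]] = {n: [] for n in names}
        for name in names:
            state = views[name]
            if len(state.unlabeled) == 0:
                terminated_early = True
                log.info("view %s unlabeled pool exhausted at iteration %d", name, iteration)
                continue
            ids = state.unlabeled.ids
            score_map = dict(zip(ids, state.classifier.score(ids, dataset)))
            n_pos = config.mvct_pos_per_iteration
            n_neg = config.mvct_neg_per_iteration
            remaining = dict(score_map)
            for _ in range(max(n_pos, n_neg)):
                pos_id, neg_id = select_confident(remaining)
                if n_pos > 0 and pos_id is not None:
                    picks[name].append((pos_id, POSITIVE, remaining.pop(pos_id)))
                    n_pos -= 1
                if n_neg > 0 and neg_id is not None:
                    picks[name].append((neg_id, NEGATIVE, remaining.pop(neg_id)))
                    n_neg -= 1
                if not remaining:
                    break
        if all(not picks[n] for n in names):
            terminated_early = True
            break

        # resolve cross-view collisions: same sample picked by both views
        chosen: dict[str, tuple[str, int, float]] = {}  # id -> (selecting view, label, score)
        for name in names:
            for sample_id, label, score in picks[name]:
                if sample_id in chosen:
                    other_view, other_label, other_score = chosen[sample_id]
                    event = {
                        "iteration": iteration,
                        "id": sample_id,
                        "views": [other_view, name],
                        "labels": [other_label, label],
                    }
                    if label != other_label:
                        # higher confidence (distance from 0.5) wins for both pools
                        if abs(score - 0.5) > abs(other_score - 0.5):
                            chosen[sample_id] = (name, label, score)
                        event["resolved_label"] = chosen[sample_id][1]
                        log.warning("pseudo-label conflict on %s: %s", sample_id, event)
                    collisions.append(event)
                else:
                    chosen[sample_id] = (name, label, score)

        added = {n: {"positive": [], "negative": []} for n in names}
        correct = total = 0
        for sample_id, (selector, label, score) in chosen.items():
            target = alternate[selector]
            collided = any(
                c["id"] == sample_id and c["iteration"] == iteration for c in collisions
            )
            targets = names if collided else [target]
            for tgt in targets:
                if sample_id not in views[tgt].labeled:
                    views[tgt].labeled.add(
                        sample_id, label, source="cotrain_pseudo", confidence=score
                    )
                    side = "positive" if label == POSITIVE else "negative"
                    added[tgt][side].append(sample_id)
            truth = dataset.true_label(sample_id)
            if truth is not None:
                total += 1
                correct += int(truth == label)
            for n in names:  # removed from BOTH unlabeled pools
                views[n].unlabeled.discard(sample_id)

        for n in names:
            views[n].check_disjoint()
            views[n].labeled.require_both_classes()

        fit_all()
        records.append(snapshot(iteration, added, correct, total))

    return CoTrainingResult(
        views=views,
        records=records,
        collisions=collisions,
        terminated_early=terminated_early,
    )
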