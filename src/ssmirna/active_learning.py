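"""Stage 2 — pool-based active learning with uncertainty sampling.

The active learner starts from the union of the co-training views'
final labeled pools (with defaults and no cross-view collisions,
54 working labels: the 10-sample seed plus 22 pseudo-labels per view)
and the intersection of their unlabeled pools. It trains on the
*integrated* feature set — all views' columns concatenated — and at
each iteration asks the oracle for the true labels of the least
confident predicted positive and predicted negative, i.e. the samples
closest to the 0.5 decision boundary. Uncertainty querying is the
built-in strategy (certainty-based querying is deliberately not);
the query function is injectable for experimentation.

The oracle is simulated by revealing withheld ground truth, and the
:class:`OracleLedger` accounts for every reveal: seed labels plus two
per completed iteration — with defaults, 10 + 22 = 32, the method's
entire labeling budget. Pseudo-labels are free and never enter the
ledger; when a queried sample already carries a pseudo-label, truth
overwrites it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

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
from .cotraining import CoTrainingResult
from .evaluation import auprc

log = logging.getLogger(__name__)

__all__ = [
    "OracleLedger",
    "SimulatedOracle",
    "PendingAnnotationOracle",
    "ALResult",
    "form_al_seed",
    "query_uncertain",
    "run_active_learning",
]


@dataclass
class OracleLedger:
    """Audit trail of oracle reveals; total = the consumed labeling budget."""

    entries: list[dict] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.entries)

    @property
    def queried_ids(self) -> list[str]:
        return [e["id"] for e in self.entries]

    def record(self, sample_id: str, label: int | None, iteration: int | None) -> None:
        if sample_id in set(self.queried_ids):
            raise ValueError(f"sample {sample_id!r} already labeled by the oracle")
        self.entries.append({"id": sample_id, "label": label, "iteration": iteration})


class SimulatedOracle:
    """Reveals the withheld true label of a sample, once, against a ledger."""

    def __init__(self, dataset: Dataset, ledger: OracleLedger | None = None):
        self.dataset = dataset
        self.ledger = ledger if ledger is not None else OracleLedger()

    def label(self, sample_id: str, iteration: int | None = None) -> int:
        truth = self.dataset.true_label(sample_id)
        if truth is None:
            raise ValueError(
                f"sample {sample_id!r} has no withheld ground truth; "
                "use PendingAnnotationOracle for real deployments"
            )
        self.ledger.record(sample_id, truth, iteration)
        return truth


class PendingAnnotationOracle:
    """Deployment-mode oracle: emits a worklist instead of labels.

    Every query becomes a pending-annotation record (for wet-lab
    follow-up); ``label`` returns ``None`` and the caller must stop
    growing the pool with that sample.
    """

    def __init__(self):
        self.pending: list[dict] = []
        self.ledger = OracleLedger()

    def label(self, sample_id: str, iteration: int | None = None) -> None:
        self.pending.append({"id": sample_id, "iteration": iteration})
        return None


@dataclass
class ALResult:
    """Per-iteration queries/labels/AUPRC plus the final classifier."""

    records: list[dict]
    classifier: ClassifierHandle
    labeled: LabeledPool
    unlabeled: UnlabeledPool
    ledger: OracleLedger
    collisions: list[dict] = field(default_factory=list)
    terminated_early: bool = False

    def curve(self) -> list[tuple[int, float]]:
        return [(r["iteration"], r["holdout_auprc"]) for r in self.records]

    @property
    def final_auprc(self) -> float:
        return self.records[-1]["holdout_auprc"]


def form_al_seed(result: CoTrainingResult) -> tuple[LabeledPool, UnlabeledPool, list[dict]]:
    """Hand off from co-training: union the labeled pools, intersect the rest.

    Duplicate ids (the shared seed, plus any cross-view collisions)
    collapse to one entry; if the two views committed conflicting
    working labels for the same id, the higher-confidence one wins and
    the conflict is returned for logging. The unlabeled pool is the
    intersection of the views' unlabeled pools.
    """
    names = result.view_names
    if len(names) != 2:
        raise ValueError("expected exactly two views")
    a, b = (result.views[n] for n in names)

    labeled = LabeledPool()
    conflicts: list[dict] = []
    for sample_id in a.labeled.ids:
        e = a.labeled.entry(sample_id)
        labeled.add(sample_id, e.label, source=e.source, confidence=e.confidence)
    for sample_id in b.labeled.ids:
        e = b.labeled.entry(sample_id)
        if sample_id not in labeled:
            labeled.add(sample_id, e.label, source=e.source, confidence=e.confidence)
            continue
        kept = labeled.entry(sample_id)
        if kept.label != e.label:
            event = {"id": sample_id, "labels": [kept.label, e.label]}
            if abs(e.confidence - 0.5) > abs(kept.confidence - 0.5):
                labeled.replace(sample_id, e.label, e.source, e.confidence)
            event["resolved_label"] = labeled.label_of(sample_id)
            conflicts.append(event)
            log.warning("conflicting working labels at handoff: %s", event)

    unlabeled = a.unlabeled.intersection(b.unlabeled)
    clash = [i for i in unlabeled if i in labeled]
    for i in clash:  # defensive; the both-pool removal rule should prevent this
        unlabeled.discard(i)
    return labeled, unlabeled, conflicts


def query_uncertain(
    scores: dict[str, float], threshold: float = 0.5
) -> tuple[str | None, str | None]:
    """Least confident predicted positive and predicted negative.

    Among samples scoring >= ``threshold``, the one minimizing
    ``score - threshold``; among those below, the one minimizing
    ``threshold - score``. Ties break to the lexicographically smallest
    id. If either side is empty, falls back to the two samples closest
    to the boundary overall (logged); a singleton pool yields one query.
    """
    if not scores:
        return None, None
    ids = sorted(scores)
    if len(ids) == 1:
        only = ids[0]
        if scores[only] >= threshold:
            return only, None
        return None, only
    pos_side = [i for i in ids if scores[i] >= threshold]
    neg_side = [i for i in ids if scores[i] < threshold]
    if pos_side and neg_side:
        pos = min(pos_side, key=lambda i: (scores[i] - threshold, i))
        neg = min(neg_side, key=lambda i: (threshold - scores[i], i))
        return pos, neg
    # fallback: both queries taken from the boundary-nearest samples overall
    log.info("uncertainty query fallback: one side of the boundary is empty")
    by_distance = sorted(ids, key=lambda i: (abs(scores[i] - threshold), i))
    return by_distance[0], by_distance[1]


def run_active_learning(
    dataset: Dataset,
    labeled: LabeledPool,
    unlabeled: UnlabeledPool,
    config: ExperimentConfig,
    rng: np.random.Generator,
    holdout: Dataset | None = None,
    oracle: SimulatedOracle | PendingAnnotationOracle | None = None,
    query_strategy: Callable[[dict[str, float]], tuple[str | None, str | None]] = query_uncertain,
) -> ALResult:
    """Run the uncertainty-sampling stage on the integrated feature set.

    Record 0 is the classifier fitted on the incoming pool; records
    1..n follow each iteration's two oracle reveals and refit. The
    stage stops early (logged, not an error) when the unlabeled pool
    is exhausted.
    """
    config.validate()
    labeled = labeled.copy()
    unlabeled = unlabeled.copy()
    if oracle is None:
        oracle = SimulatedOracle(dataset)
    ledger = oracle.ledger

    repetition_seed = derive_seed(rng)

    def fit() -> ClassifierHandle:
        seed = (
            repetition_seed
            if config.classifier_reseed == "per_repetition"
            else derive_seed(rng)
        )
        handle = ClassifierHandle(None, n_trees=config.n_trees, random_state=seed)
        return handle.fit(labeled, dataset)

    def holdout_auprc(handle: ClassifierHandle) -> float:
        if holdout is None or len(holdout) == 0:
            return float("nan")
        ids = holdout.ids
        return auprc(handle.score(ids, holdout), [holdout.true_label(i) for i in ids])

    classifier = fit()
    records = [
        {
            "iteration": 0,
            "queried_positive": [],
            "queried_negative": [],
            "revealed": {},
            "holdout_auprc": holdout_auprc(classifier),
            "n_labeled": len(labeled),
            "oracle_count": ledger.total,
        }
    ]
    terminated_early = False

    for iteration in range(1, config.al_iterations + 1):
        if len(unlabeled) == 0:
            terminated_early = True
            log.info("unlabeled pool exhausted before AL iteration %d", iteration)
            break
        ids = unlabeled.ids
        score_map = dict(zip(ids, classifier.score(ids, dataset)))

        queries_pos: list[str] = []
        queries_neg: list[str] = []
        remaining = dict(score_map)
        n_pos = config.al_pos_per_iteration
        n_neg = config.al_neg_per_iteration
        for _ in range(max(n_pos, n_neg)):
            pos_id, neg_id = query_strategy(remaining)
            if n_pos > 0 and pos_id is not None:
                queries_pos.append(pos_id)
                remaining.pop(pos_id)
                n_pos -= 1
            if n_neg > 0 and neg_id is not None and neg_id in remaining:
                queries_neg.append(neg_id)
                remaining.pop(neg_id)
                n_neg -= 1
            if not remaining:
                break

        revealed: dict[str, int] = {}
        for sample_id in queries_pos + queries_neg:
            truth = oracle.label(sample_id, iteration)
            unlabeled.discard(sample_id)
            if truth is None:  # deployment mode: worklist only, no pool growth
                continue
            revealed[sample_id] = truth
            if sample_id in labeled:
                labeled.replace(sample_id, truth, source="oracle")
            else:
                labeled.add(sample_id, truth, source="oracle")

        classifier = fit()
        records.append(
            {
                "iteration": iteration,
                "queried_positive": queries_pos,
                "queried_negative": queries_neg,
                "revealed": revealed,
                "holdout_auprc": holdout_auprc(classifier),
                "n_labeled": len(labeled),
                "oracle_count": ledger.total,
            }
        )

    return ALResult(
        records=records,
        classifier=classifier,
        labeled=labeled,
        unlabeled=unlabeled,
        ledger=ledger,
        terminated_early=terminated_early,
    )
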