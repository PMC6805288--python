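"""Orchestration of the dual-stage experiment.

One repetition: stratified 80/20 holdout split -> seed draw (5+/5-)
-> co-training (stage 1, free pseudo-labels) -> handoff (union of
labeled pools, intersection of unlabeled pools) -> active learning
(stage 2, 2 oracle labels per iteration) -> three checkpoint AUPRCs on
the frozen holdout. The checkpoints all use the integrated feature set
so they are comparable:

* ``baseline`` — classifier trained on the 10-sample seed alone;
* ``post_mvct`` — trained on the co-training-augmented pool (54 with
  defaults);
* ``post_al`` — the final active-learning classifier (the method's
  reported performance).

The oracle budget of a default run is exactly 32 (10 seed + 22 AL);
co-training consumes none.

Summaries repeat the whole pipeline with re-randomized seed draws
(default 100 repetitions). The holdout is frozen once per dataset by
default so that repetition-to-repetition variance isolates the seed
draw; per-repetition resplitting is available via ``resplit_per_rep``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .active_learning import (
    ALResult,
    OracleLedger,
    SimulatedOracle,
    form_al_seed,
    run_active_learning,
)
from .core import (
    ClassifierHandle,
    Dataset,
    ExperimentConfig,
    LabeledPool,
    derive_seed,
)
from .cotraining import CoTrainingResult, draw_seed, run_mvct
from .evaluation import LearningCurve, auprc, build_curve

log = logging.getLogger(__name__)

__all__ = [
    "PipelineResult",
    "RepetitionSummary",
    "holdout_split",
    "run_dual_stage",
    "run_repetitions",
]

CHECKPOINTS = ("baseline", "post_mvct", "post_al")


def holdout_split(
    dataset: Dataset, fraction: float, rng: np.random.Generator
) -> tuple[Dataset, Dataset]:
    """Stratified train/holdout split on ground-truth class.

    Requires every class (including unknown-label samples, which are
    kept in the training partition) to be splittable; classes with
    fewer than 2 members cannot be stratified.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"holdout fraction must be in (0, 1), got {fraction}")
    known = dataset.labels.dropna()
    counts = known.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to form a holdout")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"class(es) {small} have < 2 members; cannot stratify")
    ids = list(known.index)
    labels = known.to_numpy(dtype=int)
    train_ids, test_ids = train_test_split(
        ids,
        test_size=fraction,
        stratify=labels,
        random_state=derive_seed(rng),
    )
    unknown_ids = [i for i in dataset.ids if i not in set(known.index)]
    train = dataset.subset(sorted(train_ids, key=dataset.ids.index) + unknown_ids)
    test = dataset.subset(sorted(test_ids, key=dataset.ids.index))
    return train, test


@dataclass
class PipelineResult:
    """Everything one dual-stage repetition produced."""

    cotraining: CoTrainingResult
    active_learning: ALResult
    checkpoints: dict[str, float]
    ledger: OracleLedger
    config: ExperimentConfig
    master_seed: int | None = None
    handoff_conflicts: list[dict] = field(default_factory=list)

    @property
    def oracle_budget(self) -> int:
        return self.ledger.total

    def mvct_curve(self, view: str) -> LearningCurve:
        records = [
            {
                "iteration": r.iteration,
                "metric": r.holdout_auprc[view],
                "n_labeled": r.n_labeled[view],
                "oracle_count": 0,
            }
            for r in self.cotraining.records
        ]
        return build_curve(records, stage=f"mvct:{view}")

    def al_curve(self) -> LearningCurve:
        records = [
            {
                "iteration": r["iteration"],
                "metric": r["holdout_auprc"],
                "n_labeled": r["n_labeled"],
                "oracle_count": r["oracle_count"],
            }
            for r in self.active_learning.records
        ]
        return build_curve(records, stage="active_learning")


def _integrated_checkpoint(
    pool: LabeledPool,
    train: Dataset,
    holdout: Dataset,
    config: ExperimentConfig,
    seed: int,
) -> float:
    handle = ClassifierHandle(None, n_trees=config.n_trees, random_state=seed)
    handle.fit(pool, train)
    ids = holdout.ids
    return auprc(handle.score(ids, holdout), [holdout.true_label(i) for i in ids])


def run_dual_stage(
    dataset: Dataset,
    config: ExperimentConfig,
    rng: np.random.Generator,
    holdout: Dataset | None = None,
) -> PipelineResult:
    """Run one repetition of the full dual-stage pipeline.

    If ``holdout`` is None, ``dataset`` is split here (stratified,
    ``config.holdout_fraction``); otherwise ``dataset`` is taken as the
    training partition and ``holdout`` as the frozen test partition.
    """
    config.validate()
    if holdout is None:
        train, holdout = holdout_split(dataset, config.holdout_fraction, rng)
    else:
        train = dataset

    checkpoint_seed = derive_seed(rng)

    # stage 0: seed draw, counted against the oracle budget
    views = draw_seed(train, config, rng)
    first_view = next(iter(views.values()))
    ledger = OracleLedger()
    for sample_id in first_view.labeled.ids:
        ledger.record(sample_id, train.true_label(sample_id), iteration=0)

    baseline = _integrated_checkpoint(
        first_view.labeled, train, holdout, config, checkpoint_seed
    )

    # stage 1: co-training (no oracle cost)
    cotraining = run_mvct(train, config, rng, holdout=holdout, views=views)

    # handoff
    labeled, unlabeled, conflicts = form_al_seed(cotraining)
    post_mvct = _integrated_checkpoint(labeled, train, holdout, config, checkpoint_seed)

    # stage 2: active learning against the simulated oracle
    oracle = SimulatedOracle(train, ledger)
    al_result = run_active_learning(
        train, labeled, unlabeled, config, rng, holdout=holdout, oracle=oracle
    )

    checkpoints = {
        "baseline": baseline,
        "post_mvct": post_mvct,
        "post_al": al_result.final_auprc,
    }
    completed = len(al_result.records) - 1
    expected = ledger.total
    seed_count = config.seed_pos + config.seed_neg
    per_iter = config.al_pos_per_iteration + config.al_neg_per_iteration
    shortfall = sum(
        per_iter - len(r["revealed"]) for r in al_result.records[1:]
    )
    assert expected == seed_count + per_iter * completed - shortfall, (
        "oracle budget identity violated"
    )

    return PipelineResult(
        cotraining=cotraining,
        active_learning=al_result,
        checkpoints=checkpoints,
        ledger=ledger,
        config=config,
        handoff_conflicts=conflicts,
    )


@dataclass
class RepetitionSummary:
    """Mean/sd checkpoint AUPRCs and mean per-iteration curves over repetitions."""

    checkpoint_stats: pd.DataFrame  # index: checkpoint; columns: mean, sd, n
    mvct_curves: pd.DataFrame  # columns: view, iteration, mean, sd
    al_curve: pd.DataFrame  # columns: iteration, mean, sd
    per_repetition: pd.DataFrame  # one row per repetition: the three checkpoints
    oracle_budget: int
    config: ExperimentConfig
    master_seed: int

    def checkpoint_mean(self, name: str) -> float:
        return float(self.checkpoint_stats.loc[name, "mean"])


def run_repetitions(
    dataset: Dataset,
    config: ExperimentConfig,
    n_reps: int | None = None,
    master_seed: int = 0,
    resplit_per_rep: bool = False,
) -> RepetitionSummary:
    """Repeat the dual-stage pipeline with re-randomized seed draws.

    The holdout split is frozen once per dataset (default) so the
    reported sd reflects seed-draw variation; set ``resplit_per_rep``
    to also re-randomize the split in every repetition.
    """
    config.validate()
    if n_reps is None:
        n_reps = config.repetitions
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    root = np.random.SeedSequence(master_seed)
    split_seed, *rep_seeds = root.spawn(n_reps + 1)
    train = holdout = None
    if not resplit_per_rep:
        train, holdout = holdout_split(
            dataset, config.holdout_fraction, np.random.default_rng(split_seed)
        )

    checkpoint_rows = []
    mvct_rows = []
    al_rows = []
    budget = None
    for rep, seed_seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seed_seq)
        if resplit_per_rep:
            result = run_dual_stage(dataset, config, rng)
        else:
            result = run_dual_stage(train, config, rng, holdout=holdout)
        checkpoint_rows.append({"repetition": rep, **result.checkpoints})
        for view in result.cotraining.view_names:
            for iteration, metric in result.cotraining.curve(view):
                mvct_rows.append(
                    {"repetition": rep, "view": view, "iteration": iteration, "auprc": metric}
                )
        for iteration, metric in result.active_learning.curve():
            al_rows.append({"repetition": rep, "iteration": iteration, "auprc": metric})
        budget = result.oracle_budget if budget is None else budget
        if result.oracle_budget != budget:
            log.warning(
                "oracle budget varies across repetitions (%d vs %d)",
                result.oracle_budget,
                budget,
            )

    per_rep = pd.DataFrame(checkpoint_rows).set_index("repetition")
    checkpoint_stats = pd.DataFrame(
        {
            "mean": per_rep.mean(),
            "sd": per_rep.std(ddof=1).fillna(0.0),
            "n": n_reps,
        }
    )
    mvct_frame = pd.DataFrame(mvct_rows)
    mvct_curves = (
        mvct_frame.groupby(["view", "iteration"])["auprc"]
        .agg(mean="mean", sd="std")
        .reset_index()
        .fillna({"sd": 0.0})
    )
    al_frame = pd.DataFrame(al_rows)
    al_curve = (
        al_frame.groupby("iteration")["auprc"]
        .agg(mean="mean", sd="std")
        .reset_index()
        .fillna({"sd": 0.0})
    )
    return RepetitionSummary(
        checkpoint_stats=checkpoint_stats,
        mvct_curves=mvct_curves,
        al_curve=al_curve,
        per_repetition=per_rep,
        oracle_budget=int(budget),
        config=config,
        master_seed=master_seed,
    )
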