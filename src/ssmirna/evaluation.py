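"""AUPRC computation and learning-curve assembly.

Area under the precision-recall curve is the headline metric because
pre-miRNA candidate sets are heavily imbalanced (pseudo-hairpins dwarf
true precursors), where ROC-based metrics are overly optimistic.

The AUPRC here is the step-wise average precision: with samples ranked
by descending score, it is the mean of precision-at-rank over the ranks
where a positive sits. Trapezoidal interpolation in PR space is avoided
(it is optimistic). Score ties are broken by stable input order; the
documented consequence is that permuting tied pairs can change the value
slightly, which the test suite bounds on realistic holdouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["auprc", "LearningCurve", "build_curve", "paired_improvement_test"]


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision of a ranking; in [0, 1].

    Parameters
    ----------
    scores
        Classifier scores (any monotone scale; only the ranking is used).
    labels
        Binary ground truth (1 positive, 0 negative), same length.

    Raises
    ------
    ValueError
        If lengths differ or only one class is present (precision-recall
        analysis is undefined without both classes).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError(
            f"scores and labels must be equal-length 1-d arrays, "
            f"got {scores.shape} and {labels.shape}"
        )
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes required for AUPRC ({n_pos} positives, {n_neg} negatives)"
        )
    # stable sort on descending score: ties keep input order
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    hits = np.cumsum(ranked)
    ranks = np.arange(1, len(ranked) + 1)
    precision_at_rank = hits / ranks
    value = float(precision_at_rank[ranked == 1].sum() / n_pos)
    assert 0.0 <= value <= 1.0
    return value


@dataclass
class CurvePoint:
    """One learning-curve sample: metric plus pool bookkeeping."""

    iteration: int
    metric: float
    n_labeled: int = 0
    oracle_count: int = 0
    extra: dict = field(default_factory=dict)


@dataclass
class LearningCurve:
    """Per-iteration performance for one stage, iterations strictly increasing."""

    stage: str
    points: list[CurvePoint]

    def __post_init__(self) -> None:
        iters = [p.iteration for p in self.points]
        if any(b <= a for a, b in zip(iters, iters[1:])):
            raise ValueError("curve iterations must be strictly increasing")
        for p in self.points:
            if not (0.0 <= p.metric <= 1.0):
                raise ValueError(f"metric out of [0,1] at iteration {p.iteration}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def iterations(self) -> list[int]:
        return [p.iteration for p in self.points]

    @property
    def metrics(self) -> list[float]:
        return [p.metric for p in self.points]

    def metric_at(self, iteration: int) -> float:
        for p in self.points:
            if p.iteration == iteration:
                return p.metric
        raise KeyError(f"no point at iteration {iteration}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {
                "iteration": p.iteration,
                "auprc": p.metric,
                "n_labeled": p.n_labeled,
                "oracle_count": p.oracle_count,
            }
            row.update(p.extra)
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame.insert(0, "stage", self.stage)
        return frame


def build_curve(records: Sequence[dict], stage: str = "stage") -> LearningCurve:
    """Assemble a curve from per-iteration records (sorted; duplicates error).

    Each record needs ``iteration`` and ``metric``; ``n_labeled``,
    ``oracle_count`` and any extra keys are carried through.
    """
    if not records:
        raise ValueError("cannot build a learning curve from zero records")
    iters = [r["iteration"] for r in records]
    if len(set(iters)) != len(iters):
        dupes = sorted({i for i in iters if iters.count(i) > 1})
        raise ValueError(f"duplicate iteration index: {dupes}")
    points = [
        CurvePoint(
            iteration=int(r["iteration"]),
            metric=float(r["metric"]),
            n_labeled=int(r.get("n_labeled", 0)),
            oracle_count=int(r.get("oracle_count", 0)),
            extra={
                k: v
                for k, v in r.items()
                if k not in ("iteration", "metric", "n_labeled", "oracle_count")
            },
        )
        for r in sorted(records, key=lambda r: r["iteration"])
    ]
    return LearningCurve(stage=stage, points=points)


def paired_improvement_test(
    final: Sequence[float], initial: Sequence[float]
) -> tuple[float, float]:
    """Paired t-test of per-repetition final vs initial metric.

    Returns ``(t_statistic, one_sided_p)`` for the alternative
    "final > initial". Pairs repetitions, which is the natural pairing
    when each repetition shares its seed draw across the two checkpoints.
    """
    final = np.asarray(final, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if final.shape != initial.shape:
        raise ValueError("final and initial must pair up one repetition each")
    result = stats.ttest_rel(final, initial, alternative="greater")
    return float(result.statistic), float(result.pvalue)
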