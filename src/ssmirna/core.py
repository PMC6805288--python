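"""Shared domain types and the probabilistic-classifier contract.

The two learning stages (multi-view co-training, then active learning)
both operate on the same primitives defined here:

* :class:`Dataset` — samples described by two (or more) disjoint feature
  views, each a numeric table indexed by sample id, plus ground-truth
  labels that may be withheld from the learner.
* :class:`LabeledPool` / :class:`UnlabeledPool` — the bookkeeping
  containers whose growth the whole protocol is about.
* :class:`ClassifierHandle` — a fit/score wrapper around an injectable
  probabilistic classifier; the default is a 500-tree random forest with
  otherwise-default hyperparameters.
* :class:`ExperimentConfig` — every protocol knob (seed-set size,
  iteration counts, holdout fraction, repetitions, tree count).

Scores are used only as a ranking and as a distance from the 0.5
decision threshold; nothing downstream depends on probability
calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "SampleRecord",
    "Dataset",
    "LabeledPool",
    "PoolEntry",
    "UnlabeledPool",
    "ClassifierHandle",
    "ExperimentConfig",
    "DegenerateLabeledPoolError",
]

#: Working-label encoding used throughout: 1 = positive (true pre-miRNA),
#: 0 = negative (pseudo-hairpin). Ground truth may additionally be
#: ``None`` (unknown).
POSITIVE = 1
NEGATIVE = 0

#: Admissible provenance tags for a working label.
LABEL_SOURCES = ("seed", "cotrain_pseudo", "oracle", "none")


class DegenerateLabeledPoolError(ValueError):
    """Raised when a labeled pool is missing one of the two classes."""


@dataclass(frozen=True)
class SampleRecord:
    """One candidate pre-miRNA: id, per-view feature vectors, ground truth.

    ``true_label`` is 1/0 or ``None`` when unknown; ``label_source``
    records how the current working label (if any) was obtained.
    """

    id: str
    features_by_view: Mapping[str, np.ndarray]
    true_label: int | None = None
    label_source: str = "none"

    def __post_init__(self) -> None:
        if self.label_source not in LABEL_SOURCES:
            raise ValueError(f"unknown label_source {self.label_source!r}")
        if self.true_label not in (POSITIVE, NEGATIVE, None):
            raise ValueError(f"true_label must be 1, 0 or None, got {self.true_label!r}")


class Dataset:
    """Samples described by named, column-disjoint feature views.

    Parameters
    ----------
    views
        Mapping view name -> numeric DataFrame. All views must share an
        identical index of sample ids, and their column sets must be
        disjoint (the views are meant to be independent descriptions of
        the same samples).
    labels
        Ground-truth labels indexed like the views; values 1, 0 or NA
        (unknown). These are *withheld* truth: the learner only sees
        them through the seed draw or a (simulated) oracle.
    """

    def __init__(self, views: Mapping[str, pd.DataFrame], labels: pd.Series):
        if not views:
            raise ValueError("at least one view is required")
        names = list(views)
        index = views[names[0]].index
        if index.has_duplicates:
            dupes = index[index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        seen_cols: set[str] = set()
        for name, frame in views.items():
            if not frame.index.equals(index):
                raise ValueError(f"view {name!r} index differs from view {names[0]!r}")
            overlap = seen_cols.intersection(frame.columns)
            if overlap:
                raise ValueError(f"views share feature columns: {sorted(overlap)}")
            seen_cols.update(frame.columns)
        self.views: dict[str, pd.DataFrame] = {
            name: frame.astype(float) for name, frame in views.items()
        }
        self.labels = labels.reindex(index).astype("Int64")
        self._index = index

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self._index)

    @property
    def view_names(self) -> list[str]:
        return list(self.views)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def true_label(self, sample_id: str) -> int | None:
        value = self.labels.loc[sample_id]
        return None if pd.isna(value) else int(value)

    def labeled_ids(self) -> list[str]:
        """Ids whose ground truth is known (available to seed draw / oracle)."""
        return list(self.labels.dropna().index)

    def matrix(self, ids: Sequence[str], view: str | None = None) -> pd.DataFrame:
        """Feature matrix for ``ids``; ``view=None`` concatenates all views.

        The concatenation (the "integrated feature set") preserves view
        order and column order within each view.
        """
        if view is not None:
            frame = self.views[view]
        else:
            frame = pd.concat(list(self.views.values()), axis=1)
        missing = [i for i in ids if i not in frame.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return frame.loc[list(ids)]

    def subset(self, ids: Sequence[str]) -> "Dataset":
        ids = list(ids)
        return Dataset(
            {name: frame.loc[ids] for name, frame in self.views.items()},
            self.labels.loc[ids],
        )

    # -- record conversion -----------------------------------------------
    def to_records(self) -> list[SampleRecord]:
        records = []
        for sample_id in self._index:
            records.append(
                SampleRecord(
                    id=str(sample_id),
                    features_by_view={
                        name: frame.loc[sample_id].to_numpy()
                        for name, frame in self.views.items()
                    },
                    true_label=self.true_label(sample_id),
                )
            )
        return records

    @classmethod
    def from_records(
        cls, records: Sequence[SampleRecord], feature_names: Mapping[str, Sequence[str]]
    ) -> "Dataset":
        ids = [r.id for r in records]
        views = {
            view: pd.DataFrame(
                [r.features_by_view[view] for r in records],
                index=ids,
                columns=list(cols),
            )
            for view, cols in feature_names.items()
        }
        labels = pd.Series(
            [r.true_label for r in records], index=ids, dtype="Int64"
        )
        return cls(views, labels)


@dataclass(frozen=True)
class PoolEntry:
    """A committed working label with its provenance and confidence.

    ``confidence`` is the classifier score behind a pseudo-label (distance
    from 0.5 is what matters for collision resolution); oracle and seed
    labels carry confidence 1.0.
    """

    label: int
    source: str = "seed"
    confidence: float = 1.0


class LabeledPool:
    """Ordered set of (sample id, working label); no id appears twice."""

    def __init__(self, entries: Mapping[str, PoolEntry] | None = None):
        self._entries: dict[str, PoolEntry] = dict(entries or {})

    def add(self, sample_id: str, label: int, source: str = "seed", confidence: float = 1.0) -> None:
        if sample_id in self._entries:
            raise ValueError(f"sample {sample_id!r} already in labeled pool")
        if label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"working label must be 1 or 0, got {label!r}")
        self._entries[sample_id] = PoolEntry(label, source, confidence)

    def replace(self, sample_id: str, label: int, source: str, confidence: float = 1.0) -> None:
        """Overwrite an existing entry (oracle truth beats a pseudo-label)."""
        if sample_id not in self._entries:
            raise KeyError(sample_id)
        self._entries[sample_id] = PoolEntry(label, source, confidence)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    @property
    def ids(self) -> list[str]:
        return list(self._entries)

    def entry(self, sample_id: str) -> PoolEntry:
        return self._entries[sample_id]

    def label_of(self, sample_id: str) -> int:
        return self._entries[sample_id].label

    @property
    def n_positive(self) -> int:
        return sum(1 for e in self._entries.values() if e.label == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for e in self._entries.values() if e.label == NEGATIVE)

    def labels(self) -> pd.Series:
        return pd.Series(
            {i: e.label for i, e in self._entries.items()}, dtype=int
        ).reindex(self.ids)

    def copy(self) -> "LabeledPool":
        return LabeledPool(self._entries)

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            missing = "positive" if self.n_positive == 0 else "negative"
            raise DegenerateLabeledPoolError(
                f"degenerate labeled pool: no {missing} examples "
                f"({self.n_positive}+/{self.n_negative}-)"
            )


class UnlabeledPool:
    """Ordered set of sample ids awaiting a label; disjoint from labeled pools."""

    def __init__(self, ids: Iterable[str] = ()):
        self._ids: dict[str, None] = dict.fromkeys(ids)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._ids

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self._ids)

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def discard(self, sample_id: str) -> None:
        self._ids.pop(sample_id, None)

    def copy(self) -> "UnlabeledPool":
        return UnlabeledPool(self._ids)

    def intersection(self, other: "UnlabeledPool") -> "UnlabeledPool":
        return UnlabeledPool(i for i in self._ids if i in other)


class ClassifierHandle:
    """A fit/score contract over one view (or the integrated feature set).

    The default backend is scikit-learn's random forest with
    ``n_estimators`` trees (500 unless configured otherwise) and all
    other hyperparameters at their defaults. Any estimator exposing
    ``fit(X, y)`` / ``predict_proba(X)`` may be injected through
    ``estimator_factory``; it must accept a ``random_state`` keyword so
    refits are reproducible.

    Refitting with the same pool, dataset and ``random_state`` yields
    bitwise-identical scores.
    """

    def __init__(
        self,
        view: str | None,
        n_trees: int = 500,
        random_state: int = 0,
        estimator_factory=None,
    ):
        self.view = view
        self.n_trees = int(n_trees)
        self.random_state = int(random_state)
        self._factory = estimator_factory
        self.model = None
        self.feature_columns: list[str] | None = None
        self.training_ids: list[str] | None = None

    def _make_estimator(self):
        if self._factory is not None:
            return self._factory(random_state=self.random_state)
        return RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state, n_jobs=1
        )

    @property
    def is_fitted(self) -> bool:
        return self.model is not None

    def fit(self, pool: LabeledPool, dataset: Dataset) -> "ClassifierHandle":
        """Train on the pool's working labels; requires both classes present."""
        pool.require_both_classes()
        X = dataset.matrix(pool.ids, view=self.view)
        _check_finite(X)
        y = pool.labels().to_numpy()
        model = self._make_estimator()
        model.fit(X.to_numpy(), y)
        self.model = model
        self.feature_columns = list(X.columns)
        self.training_ids = pool.ids
        return self

    def score(self, ids: Sequence[str], dataset: Dataset) -> np.ndarray:
        """P(positive) for each id, order preserved; values in [0, 1]."""
        if not self.is_fitted:
            raise RuntimeError("classifier handle is not fitted")
        ids = list(ids)
        if not ids:
            return np.empty(0, dtype=float)
        X = dataset.matrix(ids, view=self.view)
        _check_finite(X)
        proba = self.model.predict_proba(X.to_numpy())
        positive_col = list(self.model.classes_).index(POSITIVE)
        scores = proba[:, positive_col]
        assert np.all((scores >= 0.0) & (scores <= 1.0))
        return scores

    def clone(self, random_state: int | None = None) -> "ClassifierHandle":
        return ClassifierHandle(
            self.view,
            n_trees=self.n_trees,
            random_state=self.random_state if random_state is None else random_state,
            estimator_factory=self._factory,
        )


def _check_finite(X: pd.DataFrame) -> None:
    values = X.to_numpy()
    bad = ~np.isfinite(values)
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite feature value for sample {X.index[row]!r} "
            f"at feature index {col} ({X.columns[col]!r})"
        )


@dataclass
class ExperimentConfig:
    """Every protocol knob, with the study's defaults.

    seed_pos / seed_neg
        Size of the initial oracle-labeled seed set (5 + 5).
    mvct_iterations
        Co-training rounds; each view contributes 1 most-confident
        positive and 1 most-confident negative per round to the
        alternate view, so each view's labeled pool grows by 2 per
        round (10 -> 32 after the default 11 rounds).
    al_iterations
        Active-learning rounds; each queries the oracle for the least
        confident predicted positive and predicted negative (2 oracle
        labels per round; 22 after the default 11 rounds, for a total
        labeling budget of 32 including the seed).
    holdout_fraction
        Stratified fraction frozen as the evaluation holdout (0.20).
    repetitions
        Number of re-randomized seed draws when summarizing (100).
    n_trees
        Random-forest size (500).
    classifier_reseed
        ``"per_repetition"`` (default): one forest random state per
        repetition, reused by every refit within it; ``"per_iteration"``:
        a fresh state for each refit. Both are deterministic under the
        master seed.
    """

    seed_pos: int = 5
    seed_neg: int = 5
    mvct_iterations: int = 11
    mvct_pos_per_iteration: int = 1
    mvct_neg_per_iteration: int = 1
    al_iterations: int = 11
    al_pos_per_iteration: int = 1
    al_neg_per_iteration: int = 1
    holdout_fraction: float = 0.20
    repetitions: int = 100
    n_trees: int = 500
    classifier_reseed: str = "per_repetition"

    def validate(self) -> None:
        for name in (
            "seed_pos",
            "seed_neg",
            "mvct_pos_per_iteration",
            "mvct_neg_per_iteration",
            "al_pos_per_iteration",
            "al_neg_per_iteration",
            "n_trees",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("mvct_iterations", "al_iterations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError(
                f"holdout_fraction must be in (0, 1), got {self.holdout_fraction}"
            )
        if self.classifier_reseed not in ("per_repetition", "per_iteration"):
            raise ValueError(
                "classifier_reseed must be 'per_repetition' or 'per_iteration'"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**dict(mapping))
        config.validate()
        return config


def derive_seed(rng: np.random.Generator) -> int:
    """Draw a 31-bit child seed from a generator (for sklearn random_state)."""
    return int(rng.integers(0, 2**31 - 1))
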