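"""Feature extraction and correlation-based feature subset selection.

Three capabilities live here:

1. The eight expression-based features of a pre-miRNA candidate,
   computed from its precursor profile (sequence, dot-bracket secondary
   structure, mature/star/loop annotation, and the small-RNA-seq read
   stacks aligned to it). These capture the footprint that Dicer
   processing leaves in the read data: real precursors show reads piled
   precisely on the mature and star arms, with 5' ends matching the
   Dicer cut sites, while pseudo-hairpins accumulate diffuse reads.

2. A minimal sequence-composition extractor (dinucleotide frequencies,
   GC content, paired fraction, hairpin-loop count) usable as a
   sequence-based view when no richer external feature table is
   supplied.

3. Correlation-based feature subset selection (CFS): Hall's merit

       merit(S) = k * mean|r_cf| / sqrt(k + k (k-1) mean|r_ff|)

   for a subset S of k features, favouring subsets whose members
   correlate with the class but not with each other, searched by
   best-first forward search with a five-expansion stale cutoff.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Interval",
    "PrecursorProfile",
    "ExpressionFeatureVector",
    "EXPRESSION_FEATURE_NAMES",
    "compute_expression_features",
    "SEQUENCE_FEATURE_NAMES",
    "compute_basic_sequence_features",
    "cfs_merit",
    "CfsResult",
    "best_first_cfs",
    "select_features_cfs",
    "correlations_for_cfs",
]


# ---------------------------------------------------------------------------
# Precursor profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """1-based closed interval on the precursor (miRBase-style coordinates)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start) + 1)

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.overlap(other.start, other.end) > 0


_RNA_ALPHABET = set("ACGU")


@dataclass
class PrecursorProfile:
    """A candidate precursor with structure, arm annotation and read evidence.

    Coordinates are 1-based closed intervals into ``sequence``. ``reads``
    are (start, end, count) stacks of identical alignments; ``library_size``
    is the total read count of the sequencing experiment, used to
    normalize precursor expression to reads per million.
    """

    id: str
    sequence: str
    structure: str
    mature: Interval
    star: Interval
    loop: Interval
    reads: list[tuple[int, int, int]]
    library_size: int
    lower_stem: Interval | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        bad = [i + 1 for i, c in enumerate(seq) if c not in _RNA_ALPHABET]
        if bad:
            raise ValueError(f"profile {self.id}: invalid RNA characters at positions {bad[:10]}")
        self.sequence = seq
        n = len(seq)
        if len(self.structure) != n:
            raise ValueError(
                f"profile {self.id}: structure length {len(self.structure)} != sequence length {n}"
            )
        depth = 0
        for i, c in enumerate(self.structure):
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
            elif c != ".":
                raise ValueError(f"profile {self.id}: bad dot-bracket char {c!r} at {i + 1}")
            if depth < 0:
                raise ValueError(f"profile {self.id}: unbalanced brackets at position {i + 1}")
        if depth != 0:
            raise ValueError(f"profile {self.id}: {depth} unclosed brackets")
        whole = Interval(1, n)
        for name in ("mature", "star", "loop"):
            region: Interval = getattr(self, name)
            if not whole.contains(region):
                raise ValueError(
                    f"profile {self.id}: {name} interval [{region.start},{region.end}] "
                    f"outside sequence of length {n}"
                )
        for a, b in itertools.combinations(("mature", "star", "loop"), 2):
            if getattr(self, a).overlaps(getattr(self, b)):
                raise ValueError(f"profile {self.id}: {a} and {b} intervals overlap")
        if self.lower_stem is not None and not whole.contains(self.lower_stem):
            raise ValueError(f"profile {self.id}: lower_stem outside sequence")
        for start, end, count in self.reads:
            if count < 1:
                raise ValueError(f"profile {self.id}: read count {count} < 1")
            if start < 1 or end > n or end < start:
                raise ValueError(
                    f"profile {self.id}: read [{start},{end}] outside precursor of length {n}"
                )
        if self.library_size < 1:
            raise ValueError(f"profile {self.id}: library_size must be >= 1")

    @property
    def total_reads(self) -> int:
        return sum(count for _, _, count in self.reads)

    def paired_positions(self) -> np.ndarray:
        """Boolean mask (0-based) of positions paired in the dot-bracket."""
        return np.array([c != "." for c in self.structure], dtype=bool)


EXPRESSION_FEATURE_NAMES = (
    "pct_mature_paired",
    "n_paired_lower_stem",
    "pct_reads_dicer_inconsistent",
    "pct_reads_loop",
    "pct_reads_mature",
    "pct_reads_star",
    "pct_reads_dicer_consistent",
    "total_reads_rpm",
)


@dataclass(frozen=True)
class ExpressionFeatureVector:
    """The eight expression-based features, in their canonical order."""

    pct_mature_paired: float
    n_paired_lower_stem: float
    pct_reads_dicer_inconsistent: float
    pct_reads_loop: float
    pct_reads_mature: float
    pct_reads_star: float
    pct_reads_dicer_consistent: float
    total_reads_rpm: float

    def __post_init__(self) -> None:
        for name in EXPRESSION_FEATURE_NAMES[:7]:
            value = getattr(self, name)
            if name.startswith("pct") and not (0.0 <= value <= 100.0):
                raise ValueError(f"{name} = {value} outside [0, 100]")
        if self.total_reads_rpm < 0:
            raise ValueError("total_reads_rpm must be >= 0")
        if abs(self.pct_reads_dicer_inconsistent + self.pct_reads_dicer_consistent - 100.0) > 1e-9:
            raise ValueError("Dicer-consistent and -inconsistent percentages must sum to 100")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in EXPRESSION_FEATURE_NAMES], dtype=float)


def _infer_lower_stem(profile: PrecursorProfile) -> list[Interval]:
    """Basal stem flanks: positions below both mature and star arms.

    Returns up to two intervals (5' flank, 3' flank); either may be
    absent when an arm abuts the precursor end.
    """
    lo = min(profile.mature.start, profile.star.start)
    hi = max(profile.mature.end, profile.star.end)
    flanks = []
    if lo > 1:
        flanks.append(Interval(1, lo - 1))
    if hi < len(profile.sequence):
        flanks.append(Interval(hi + 1, len(profile.sequence)))
    return flanks


def _assign_region(profile: PrecursorProfile, start: int, end: int) -> str | None:
    """Region with greatest overlap; ties mature > star > loop; None if no overlap."""
    overlaps = {
        "mature": profile.mature.overlap(start, end),
        "star": profile.star.overlap(start, end),
        "loop": profile.loop.overlap(start, end),
    }
    best = max(overlaps.values())
    if best == 0:
        return None
    for name in ("mature", "star", "loop"):  # priority order on ties
        if overlaps[name] == best:
            return name
    raise AssertionError("unreachable")


def compute_expression_features(
    profile: PrecursorProfile, dicer_tolerance: int = 1
) -> ExpressionFeatureVector:
    """Compute the eight expression-based features of a precursor profile.

    A read stack is assigned to the mature/star/loop region it overlaps
    most (ties resolved mature > star > loop). A read is Dicer-consistent
    iff its 5' end lies within ``dicer_tolerance`` nt of the mature or
    star 5' end; the inconsistent percentage is its complement. All read
    percentages are weighted by stack counts. Expression (feature 8) is
    total precursor reads per million library reads.

    Raises
    ------
    ValueError
        If the profile has no reads ("no expression evidence") or fails
        its structural invariants.
    """
    total = profile.total_reads
    if total == 0:
        raise ValueError(f"profile {profile.id}: no expression evidence (zero reads)")

    paired = profile.paired_positions()

    mature_slice = paired[profile.mature.start - 1 : profile.mature.end]
    pct_mature_paired = 100.0 * mature_slice.sum() / len(profile.mature)

    if profile.lower_stem is not None:
        stems = [profile.lower_stem]
    else:
        stems = _infer_lower_stem(profile)
        if not stems:
            warnings.warn(
                f"profile {profile.id}: no lower stem could be inferred; "
                "n_paired_lower_stem set to 0",
                stacklevel=2,
            )
    n_paired_lower_stem = float(
        sum(int(paired[s.start - 1 : s.end].sum()) for s in stems)
    )

    region_reads = {"mature": 0, "star": 0, "loop": 0}
    consistent = 0
    for start, end, count in profile.reads:
        region = _assign_region(profile, start, end)
        if region is not None:
            region_reads[region] += count
        five_prime = start
        if (
            abs(five_prime - profile.mature.start) <= dicer_tolerance
            or abs(five_prime - profile.star.start) <= dicer_tolerance
        ):
            consistent += count

    pct_consistent = 100.0 * consistent / total
    return ExpressionFeatureVector(
        pct_mature_paired=pct_mature_paired,
        n_paired_lower_stem=n_paired_lower_stem,
        pct_reads_dicer_inconsistent=100.0 - pct_consistent,
        pct_reads_loop=100.0 * region_reads["loop"] / total,
        pct_reads_mature=100.0 * region_reads["mature"] / total,
        pct_reads_star=100.0 * region_reads["star"] / total,
        pct_reads_dicer_consistent=pct_consistent,
        total_reads_rpm=1e6 * total / profile.library_size,
    )


# ---------------------------------------------------------------------------
# Stand-in sequence-composition features
# ---------------------------------------------------------------------------

_DINUCLEOTIDES = tuple(a + b for a in "ACGU" for b in "ACGU")

SEQUENCE_FEATURE_NAMES = tuple(f"dinuc_{d}" for d in _DINUCLEOTIDES) + (
    "gc_fraction",
    "paired_fraction",
    "loop_count",
)


def compute_basic_sequence_features(
    sequence: str, structure: str | None = None
) -> np.ndarray:
    """Sequence-composition vector: 16 dinucleotide frequencies, GC
    fraction, paired-nt fraction and hairpin-loop count.

    A deliberately small stand-in for externally computed sequence-based
    feature catalogues; any user-supplied numeric table can serve as the
    sequence view instead. Without a dot-bracket string the two
    structural entries are 0.
    """
    seq = sequence.upper().replace("T", "U")
    bad = [i + 1 for i, c in enumerate(seq) if c not in _RNA_ALPHABET]
    if bad:
        raise ValueError(f"invalid RNA characters at positions {bad[:10]}")
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")

    counts = {d: 0 for d in _DINUCLEOTIDES}
    for i in range(n - 1):
        counts[seq[i : i + 2]] += 1
    n_pairs = max(n - 1, 1)
    dinuc = np.array([counts[d] / n_pairs for d in _DINUCLEOTIDES], dtype=float)

    gc = (seq.count("G") + seq.count("C")) / n

    if structure is not None:
        if len(structure) != n:
            raise ValueError("structure length must match sequence length")
        paired_fraction = sum(1 for c in structure if c != ".") / n
        loop_count = _count_hairpin_loops(structure)
    else:
        paired_fraction = 0.0
        loop_count = 0.0

    return np.concatenate([dinuc, [gc, paired_fraction, float(loop_count)]])


def _count_hairpin_loops(structure: str) -> int:
    """Hairpin loops = maximal dot runs directly enclosed by '(' then ')'."""
    count = 0
    i = 0
    n = len(structure)
    while i < n:
        if structure[i] == "(":
            j = i + 1
            while j < n and structure[j] == ".":
                j += 1
            if j > i + 1 and j < n and structure[j] == ")":
                count += 1
            i = j if j > i + 1 else i + 1
        else:
            i += 1
    return count


# ---------------------------------------------------------------------------
# CFS: merit and best-first subset search
# ---------------------------------------------------------------------------

def cfs_merit(
    subset: Sequence[str],
    feature_class_corr: pd.Series,
    feature_feature_corr: pd.DataFrame,
) -> float:
    """Hall's CFS merit of a feature subset.

    merit = k * mean|r_cf| / sqrt(k + k (k-1) * mean|r_ff|), where the
    means run over the subset's feature-class correlations and its
    off-diagonal feature-feature correlations (absolute values, both).
    """
    if len(subset) == 0:
        raise ValueError("CFS merit of an empty subset is undefined")
    subset = list(subset)
    k = len(subset)
    r_cf = float(np.abs(feature_class_corr.loc[subset]).mean())
    if k == 1:
        r_ff = 0.0
    else:
        block = np.abs(feature_feature_corr.loc[subset, subset].to_numpy())
        r_ff = float((block.sum() - np.trace(block)) / (k * (k - 1)))
    denom = np.sqrt(k + k * (k - 1) * r_ff)
    return k * r_cf / denom


@dataclass
class CfsResult:
    """Selected subset, its merit, and the best-first search trace."""

    selected: list[str]
    merit: float
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)


def correlations_for_cfs(
    features: pd.DataFrame, labels: Sequence[int]
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Absolute Pearson correlations used by CFS.

    Feature-class correlation is the point-biserial correlation (Pearson
    against the 0/1 class indicator). Constant feature columns carry no
    correlation and are dropped with a warning rather than an error.
    """
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for CFS")
    constant = [c for c in features.columns if features[c].nunique() <= 1]
    if constant:
        log.warning("dropping constant feature columns: %s", constant)
        features = features.drop(columns=constant)
    if features.shape[1] == 0:
        raise ValueError("no non-constant features remain")
    X = features.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    x_sd = Xc.std(axis=0)
    y_sd = yc.std()
    r_cf = np.abs((Xc * yc[:, None]).mean(axis=0) / (x_sd * y_sd))
    corr = np.abs(np.corrcoef(X, rowvar=False))
    if corr.ndim == 0:  # single feature
        corr = corr.reshape(1, 1)
    cols = list(features.columns)
    return (
        pd.Series(r_cf, index=cols),
        pd.DataFrame(corr, index=cols, columns=cols),
        constant,
    )


def best_first_cfs(
    feature_class_corr: pd.Series,
    feature_feature_corr: pd.DataFrame,
    max_stale: int = 5,
) -> CfsResult:
    """Best-first forward search maximizing the CFS merit.

    Starts from the empty set, repeatedly expands the best open subset
    by one feature, and stops after ``max_stale`` consecutive expansions
    that fail to improve on the best merit seen (or when the lattice is
    exhausted). Deterministic: among equal-merit candidates the
    lexicographically smallest name set wins.
    """
    names = sorted(feature_class_corr.index)

    def merit_of(subset: frozenset) -> float:
        return cfs_merit(sorted(subset), feature_class_corr, feature_feature_corr)

    # open list of (merit, subset); expand best-first with backtracking
    open_list: list[tuple[float, frozenset]] = [(-np.inf, frozenset())]
    evaluated: dict[frozenset, float] = {frozenset(): -np.inf}
    best_subset: frozenset = frozenset()
    best_merit = -np.inf
    trace: list[tuple[tuple[str, ...], float]] = []
    stale = 0

    while open_list and stale < max_stale:
        # pop highest merit; tie-break on lexicographically smallest subset
        open_list.sort(key=lambda item: (-item[0], tuple(sorted(item[1]))))
        _, current = open_list.pop(0)
        improved = False
        for name in names:
            if name in current:
                continue
            child = current | {name}
            if child in evaluated:
                continue
            merit = merit_of(child)
            evaluated[child] = merit
            open_list.append((merit, child))
            trace.append((tuple(sorted(child)), merit))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_subset = child
                improved = True
            elif abs(merit - best_merit) <= 1e-12 and tuple(sorted(child)) < tuple(
                sorted(best_subset)
            ):
                best_subset = child  # equal merit: smallest names win
        stale = 0 if improved else stale + 1

    return CfsResult(selected=sorted(best_subset), merit=float(best_merit), trace=trace)


def select_features_cfs(
    features: pd.DataFrame,
    labels: Sequence[int],
    max_stale: int = 5,
) -> CfsResult:
    """CFS on a feature matrix: correlations, then best-first search.

    Requires at least two candidate features and both classes present;
    constant feature columns are dropped with a logged warning.
    """
    if features.shape[1] < 2:
        raise ValueError("CFS needs at least two candidate features")
    r_cf, r_ff, dropped = correlations_for_cfs(features, labels)
    result = best_first_cfs(r_cf, r_ff, max_stale=max_stale)
    result.dropped_constant = dropped
    return result
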