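"""Readers and writers: feature tables, view manifests, precursor
profiles, configs, and result serialization.

Conventions: feature tables are delimited text (TSV by default, comma
accepted) with a header row; column 1 is the sample id; the label
column takes ``1/0/?`` or ``positive/negative/unlabeled``. A view
manifest (JSON) maps each view name to its feature columns. Precursor
coordinates are 1-based closed intervals throughout (miRBase-style
annotation convention). FASTA parsing tolerates wrapped lines and both
U and T (T is mapped to U). All floating-point outputs are serialized
at 6 decimals so reruns diff cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import Dataset, ExperimentConfig
from .features import Interval, PrecursorProfile
from .pipeline import PipelineResult, RepetitionSummary

__all__ = [
    "ViewManifest",
    "read_feature_table",
    "write_feature_table",
    "read_profiles",
    "write_profiles",
    "read_config",
    "write_results",
    "write_summary",
]

FLOAT_FORMAT = "%.6f"

_LABEL_ALIASES = {
    "1": 1,
    "positive": 1,
    "pos": 1,
    "0": 0,
    "negative": 0,
    "neg": 0,
    "?": None,
    "unlabeled": None,
    "unknown": None,
    "": None,
}


@dataclass
class ViewManifest:
    """Maps view names to feature columns, plus id/label column names."""

    views: dict[str, list[str]]
    label_column: str = "label"
    id_column: str = "id"

    def validate_against(self, columns: Sequence[str]) -> None:
        seen: set[str] = set()
        for name, cols in self.views.items():
            overlap = seen.intersection(cols)
            if overlap:
                raise ValueError(f"views share columns: {sorted(overlap)}")
            seen.update(cols)
            missing = [c for c in cols if c not in columns]
            if missing:
                raise ValueError(f"view {name!r} names missing columns: {missing}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ViewManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            views={k: list(v) for k, v in payload["views"].items()},
            label_column=payload.get("label_column", "label"),
            id_column=payload.get("id_column", "id"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "views": self.views,
                    "label_column": self.label_column,
                    "id_column": self.id_column,
                },
                indent=2,
            )
            + "\n"
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as handle:
        header = handle.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def _parse_label(raw) -> int | None:
    text = str(raw).strip().lower()
    if text in ("nan", "<na>"):
        return None
    if text not in _LABEL_ALIASES:
        raise ValueError(f"unrecognized label value {raw!r}")
    return _LABEL_ALIASES[text]


def read_feature_table(path: str | Path, manifest: ViewManifest) -> Dataset:
    """Read a delimited feature table into a :class:`Dataset`.

    Row order is preserved; duplicate ids and non-numeric feature cells
    are errors naming the offender.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    if manifest.id_column not in frame.columns:
        raise ValueError(f"id column {manifest.id_column!r} not in {list(frame.columns)}")
    manifest.validate_against(frame.columns)
    ids = frame[manifest.id_column].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample ids: {dupes}")
    frame = frame.set_index(ids)

    if manifest.label_column in frame.columns:
        labels = pd.Series(
            [_parse_label(v) for v in frame[manifest.label_column]],
            index=frame.index,
            dtype="Int64",
        )
    else:
        labels = pd.Series([None] * len(frame), index=frame.index, dtype="Int64")

    views: dict[str, pd.DataFrame] = {}
    for name, cols in manifest.views.items():
        block = frame[cols]
        numeric = block.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & block.notna()
        if bad.to_numpy().any():
            row, col = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric feature cell at row {block.index[row]!r}, "
                f"column {block.columns[col]!r}: {block.iat[row, col]!r}"
            )
        views[name] = numeric.astype(float)
    return Dataset(views, labels)


def write_feature_table(
    dataset: Dataset, path: str | Path, manifest: ViewManifest | None = None
) -> ViewManifest:
    """Write a dataset as TSV (+ return the matching manifest)."""
    if manifest is None:
        manifest = ViewManifest(
            views={name: list(frame.columns) for name, frame in dataset.views.items()}
        )
    table = pd.concat(list(dataset.views.values()), axis=1)
    label_text = dataset.labels.map(lambda v: "?" if pd.isna(v) else str(int(v)))
    table.insert(0, manifest.label_column, label_text)
    table.index.name = manifest.id_column
    table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    return manifest


# ---------------------------------------------------------------------------
# Precursor profile I/O
# ---------------------------------------------------------------------------

def read_profiles(
    fasta_path: str | Path,
    structure_path: str | Path,
    annotation_path: str | Path,
    reads_path: str | Path,
    library_size: int,
) -> list[PrecursorProfile]:
    """Assemble precursor profiles from their four companion files.

    * FASTA: precursor sequences (wrapped lines fine; T mapped to U);
    * structure file: TSV of ``id<TAB>dot-bracket``;
    * annotations: TSV ``id  start  end  tag`` with tags
      mature/star/loop/lower_stem, 1-based closed coordinates;
    * reads: TSV ``id  start  end  count``.
    """
    sequences = {
        record.id: str(record.seq).upper().replace("T", "U")
        for record in SeqIO.parse(str(fasta_path), "fasta")
    }
    structures: dict[str, str] = {}
    for line in Path(structure_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, dot_bracket = line.split("\t")
        structures[name] = dot_bracket.strip()

    annotations = pd.read_csv(
        annotation_path, sep="\t", names=["id", "start", "end", "tag"], comment="#"
    )
    reads = pd.read_csv(
        reads_path, sep="\t", names=["id", "start", "end", "count"], comment="#"
    )

    profiles = []
    for name, sequence in sequences.items():
        if name not in structures:
            raise ValueError(f"no structure record for {name!r}")
        regions = {
            row["tag"]: Interval(int(row["start"]), int(row["end"]))
            for _, row in annotations[annotations["id"] == name].iterrows()
        }
        for required in ("mature", "star", "loop"):
            if required not in regions:
                raise ValueError(f"profile {name!r} missing {required} annotation")
        stacks = [
            (int(row["start"]), int(row["end"]), int(row["count"]))
            for _, row in reads[reads["id"] == name].iterrows()
        ]
        profiles.append(
            PrecursorProfile(
                id=name,
                sequence=sequence,
                structure=structures[name],
                mature=regions["mature"],
                star=regions["star"],
                loop=regions["loop"],
                lower_stem=regions.get("lower_stem"),
                reads=stacks,
                library_size=library_size,
            )
        )
    return profiles


def write_profiles(profiles: Sequence[PrecursorProfile], out_dir: str | Path) -> dict[str, Path]:
    """Write profiles as the four companion text files (round-trips with
    :func:`read_profiles`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "precursors.fa",
        "structure": out / "precursors.db.tsv",
        "annotation": out / "annotations.tsv",
        "reads": out / "reads.tsv",
    }
    with open(paths["fasta"], "w") as fasta, open(paths["structure"], "w") as struct, open(
        paths["annotation"], "w"
    ) as annot, open(paths["reads"], "w") as reads:
        for p in profiles:
            fasta.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 70):
                fasta.write(p.sequence[i : i + 70] + "\n")
            struct.write(f"{p.id}\t{p.structure}\n")
            regions = {"mature": p.mature, "star": p.star, "loop": p.loop}
            if p.lower_stem is not None:
                regions["lower_stem"] = p.lower_stem
            for tag, region in regions.items():
                annot.write(f"{p.id}\t{region.start}\t{region.end}\t{tag}\n")
            for start, end, count in p.reads:
                reads.write(f"{p.id}\t{start}\t{end}\t{count}\n")
    return paths


# ---------------------------------------------------------------------------
# Config and results
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> ExperimentConfig:
    return ExperimentConfig.from_dict(json.loads(Path(path).read_text()))


def _fmt(value: float) -> float:
    return float(FLOAT_FORMAT % value) if np.isfinite(value) else value


def write_results(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Serialize one dual-stage run: summary JSON, curve TSVs, pool state.

    Re-reading the summary JSON reproduces every reported number
    exactly (all floats already rounded to the serialized precision).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    curve_frames = [
        result.mvct_curve(view).to_frame() for view in result.cotraining.view_names
    ]
    curve_frames.append(result.al_curve().to_frame())
    curves = pd.concat(curve_frames, ignore_index=True)
    curves_path = out / "curves.tsv"
    curves.to_csv(curves_path, sep="\t", index=False, float_format=FLOAT_FORMAT)

    summary = {
        "checkpoints": {k: _fmt(v) for k, v in result.checkpoints.items()},
        "oracle_budget": result.oracle_budget,
        "labeled_pool_sizes": {
            view: len(result.cotraining.views[view].labeled)
            for view in result.cotraining.view_names
        },
        "al_final_labeled": len(result.active_learning.labeled),
        "pseudo_label_fidelity": _fmt(result.cotraining.pseudo_label_fidelity()),
        "handoff_conflicts": len(result.handoff_conflicts),
        "config": result.config.to_dict(),
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    pools = {
        "al_labeled": {
            i: {
                "label": result.active_learning.labeled.entry(i).label,
                "source": result.active_learning.labeled.entry(i).source,
            }
            for i in result.active_learning.labeled.ids
        },
        "al_unlabeled": result.active_learning.unlabeled.ids,
        "oracle_ledger": result.ledger.entries,
    }
    pools_path = out / "pools.json"
    pools_path.write_text(json.dumps(pools, indent=2) + "\n")

    return {"summary": summary_path, "curves": curves_path, "pools": pools_path}


def write_summary(summary: RepetitionSummary, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a repetition summary: stats JSON + mean-curve TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stats = {
        "checkpoints": {
            name: {
                "mean": _fmt(summary.checkpoint_stats.loc[name, "mean"]),
                "sd": _fmt(summary.checkpoint_stats.loc[name, "sd"]),
            }
            for name in summary.checkpoint_stats.index
        },
        "oracle_budget": summary.oracle_budget,
        "repetitions": int(summary.checkpoint_stats["n"].iloc[0]),
        "master_seed": summary.master_seed,
        "config": summary.config.to_dict(),
    }
    stats_path = out / "summary.json"
    stats_path.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")

    mvct_path = out / "mvct_curve.tsv"
    summary.mvct_curves.to_csv(mvct_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    al_path = out / "al_curve.tsv"
    summary.al_curve.to_csv(al_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    reps_path = out / "per_repetition.tsv"
    summary.per_repetition.to_csv(reps_path, sep="\t", float_format=FLOAT_FORMAT)
    return {"summary": stats_path, "mvct_curve": mvct_path, "al_curve": al_path, "per_repetition": reps_path}


def plot_learning_curves(summary: RepetitionSummary, out_dir: str | Path) -> Path:
    """Learning-curve figure (mean AUPRC per iteration, both stages)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for view, group in summary.mvct_curves.groupby("view"):
        axes[0].plot(group["iteration"], group["mean"], marker="o", label=str(view))
    axes[0].set_title("Stage 1: co-training")
    axes[0].set_xlabel("iteration")
    axes[0].set_ylabel("mean holdout AUPRC")
    axes[0].legend()
    axes[1].plot(summary.al_curve["iteration"], summary.al_curve["mean"], marker="o")
    axes[1].set_title("Stage 2: active learning")
    axes[1].set_xlabel("iteration")
    fig.tight_layout()
    path = out / "learning_curves.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_stage_contributions(summary: RepetitionSummary, out_dir: str | Path) -> Path:
    """Stacked-bar figure of checkpoint AUPRCs (baseline / +MVCT / +AL)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = summary.checkpoint_mean("baseline")
    mvct = summary.checkpoint_mean("post_mvct")
    al = summary.checkpoint_mean("post_al")
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(["pipeline"], [base], label=f"seed baseline ({base:.3f})")
    ax.bar(["pipeline"], [max(mvct - base, 0)], bottom=[base], label=f"+ co-training ({mvct:.3f})")
    ax.bar(
        ["pipeline"],
        [max(al - mvct, 0)],
        bottom=[max(mvct, base)],
        label=f"+ active learning ({al:.3f})",
    )
    ax.set_ylabel("mean holdout AUPRC")
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = out / "stage_contributions.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
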