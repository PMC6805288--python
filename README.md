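# ssmirna

Dual-stage semi-supervised classification of pre-miRNA candidates:
**multi-view co-training** to grow the labeled pool for free, followed
by **uncertainty-based active learning** to spend a small wet-lab
annotation budget where it matters most.

## Who this is for

Genomics groups trying to call true miRNA precursors against a flood of
pseudo-hairpins in species with few validated miRNAs. Small-RNA
sequencing yields hundreds of candidate hairpins, each describable by
two independent feature views — sequence/structure descriptors and
read-stack ("expression") features — but almost none of them labeled.
`ssmirna` implements a learning protocol for exactly that regime: it
needs only 10 known labels to start and a budget of ~2 new annotations
per iteration.

## The method

Let each candidate carry feature views $x^{(1)}$ (sequence) and
$x^{(2)}$ (expression), and let each view have its own labeled pool
$L_v$, both initialized to a shared seed of 5 positives + 5 negatives.

**Stage 1 (MVCT).** For $t = 1 \dots 11$: fit a 500-tree random forest
$f_v$ on each $L_v$; each view selects from its unlabeled pool the
sample with the highest score $\hat p(+)$ and the lowest; each selected
sample is added to the *other* view's pool with its predicted
pseudo-label and removed from both unlabeled pools. No oracle calls:
after 11 iterations $|L_v| = 10 + 22 = 32$, free of charge.

**Stage 2 (active learning).** Start from $L = L_1 \cup L_2$ (54
labels when no cross-view collision occurred) and the intersection of
the unlabeled pools, now using the integrated feature set
$[x^{(1)}, x^{(2)}]$. For $t = 1 \dots 11$: query a (simulated) oracle
for the true labels of the least confident predicted positive and
negative — the samples with scores closest to 0.5 — refit, and record
AUPRC on a frozen 20% stratified holdout. Total oracle budget:
10 seed + 22 queries = **32 true labels**.

Performance is the area under the precision-recall curve (step-wise
average precision), the right metric under the ~1:4+ class imbalance
of candidate sets. The package also ships the eight expression-based
features computed from precursor read profiles, correlation-based
feature subset selection (CFS merit + best-first search), a synthetic
two-view data generator so the whole pipeline runs with no downloads,
and a thin `ssmirna` command-line interface.

## Worked example

One full repetition on the synthetic default scenario (150 true /
600 pseudo candidates, weak sequence view, stronger expression view)
with a reduced 50-tree forest — `examples/run_dual_stage_pipeline.py`:

```python
import numpy as np
from ssmirna import (ExperimentConfig, default_scenario,
                     generate_two_view_dataset, run_dual_stage)

dataset = generate_two_view_dataset(default_scenario(), np.random.default_rng(7))
result = run_dual_stage(dataset, ExperimentConfig(n_trees=50), np.random.default_rng(0))
```

prints

```
labeled-pool sizes after co-training: {'sequence': 32, 'expression': 32}
active-learning seed size: 54
oracle budget consumed: 32
pseudo-label fidelity: 75.0%
holdout AUPRC checkpoints:
    baseline: 0.728
   post_mvct: 0.785
     post_al: 0.816
```

Reading the numbers: co-training grew each view's pool 10 → 32 with
pseudo-labels (75% of them matching the withheld truth on this run),
their union of 54 seeded active learning, and the whole run consumed
exactly 32 true labels. On the frozen holdout, the seed-only baseline
scores 0.728 AUPRC, the co-training-augmented pool lifts it to 0.785,
and active learning closes at 0.816 — each stage contributing on top
of the last.

The other scripts in `examples/` each exercise one capability:
dataset simulation, expression features from read profiles, CFS
selection, and repetition-averaged learning curves with plots. The
equivalent shell entry points are `ssmirna simulate|features|mvct|al|
pipeline|evaluate`.

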