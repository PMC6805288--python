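# Methods

## The problem

Candidate pre-miRNA sets — hairpin-folding loci pulled from small-RNA
sequencing or genomic scans — are dominated by pseudo-hairpins:
sequences that fold like a precursor but never yield a mature miRNA.
Supervised classifiers separate the two classes well, but only with
hundreds of labeled examples, which most species do not have. The
regime this package targets is the opposite one: a handful of
validated labels, a large unlabeled candidate pool, and a tight budget
for new wet-lab annotations.

## The dual-stage protocol

Each candidate carries two disjoint feature views: a sequence-based
view (composition/structure descriptors, user-supplied or the built-in
minimal extractor) and an expression-based view (the eight read-stack
features below). The protocol is:

**Stage 0 — seed.** A stratified 80/20 split freezes a holdout; from
the training side, 5 positives and 5 negatives are drawn as the seed
pool. These 10 labels count against the oracle budget.

**Stage 1 — multi-view co-training (MVCT).** Each view keeps its *own*
labeled pool, both initialized to the shared seed. Per iteration, each
view's classifier scores its unlabeled pool and nominates its most
confident predicted positive and negative; each nominee joins the
*other* view's labeled pool with the predicted (pseudo) label, at zero
oracle cost, and leaves both unlabeled pools. Pool disjointness beyond
the seed keeps the views from converging onto the same training
evidence, which would plateau the benefit. After the default 11
iterations each view holds 10 + 22 = 32 working labels.

**Stage 2 — active learning.** The union of the two labeled pools
(54 entries when no cross-view collision occurred) seeds an
uncertainty-sampling active learner over the *integrated* feature set
(all views concatenated); its unlabeled pool is the intersection of the
views' pools. Per iteration it queries a simulated oracle — withheld
ground truth — for the least confident predicted positive and negative
(samples closest to the 0.5 boundary), refits, and records holdout
AUPRC. Eleven iterations spend 22 oracle labels, closing the total
budget at 32.

Three checkpoints are evaluated on the same frozen holdout with the
same integrated feature set so they are directly comparable: the
10-label seed baseline, the post-co-training pool, and the final
active-learning classifier. Summaries repeat the whole protocol
(default 100 repetitions) with re-randomized seed draws.

### Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `seed_pos`/`seed_neg` | 5/5 | the label-scarce starting point |
| `mvct_iterations` | 11 | fixed horizon; co-training gains typically asymptote near here, and no dynamic stopping rule is built in |
| additions per view per MVCT iteration | 1+/1− | only the top-confidence pair, to keep pseudo-label quality high |
| `al_iterations` | 11 | 22 oracle labels; with the seed, a budget of 32 |
| `holdout_fraction` | 0.20 | stratified, frozen per dataset by default |
| `n_trees` | 500 | random forest size; all other forest hyperparameters are scikit-learn defaults |
| `repetitions` | 100 | seed-draw re-randomizations for mean ± sd |
| `classifier_reseed` | per_repetition | one forest random state per repetition (per-iteration reseeding available) |

### Design choices where the design was open

* **Both-pool removal.** A sample selected by either view leaves both
  views' unlabeled pools immediately. This prevents the same sample
  from later receiving a conflicting pseudo-label from the other view
  and makes the stage-2 pool intersection well defined.
* **Cross-view collisions.** If both views nominate the same sample in
  one iteration it enters both labeled pools; on a label conflict the
  higher-confidence prediction (distance from 0.5) wins for both, and
  the event is logged. Collisions are rare on realistic pools (~600
  unlabeled candidates) and shrink the stage-2 seed by one each.
* **Decision threshold.** 0.5 defines "predicted positive" for query
  side assignment; if one side of the boundary is empty the two
  overall boundary-nearest samples are queried (logged fallback).
* **Pseudo-labels in stage 2** are treated as ordinary training labels
  (not down-weighted); their provenance is retained in the pool
  entries and they never touch the oracle ledger. An oracle reveal for
  a pseudo-labeled id overwrites it with truth.
* **Checkpoint comparability.** All three checkpoints use the
  integrated feature set; stage-1 per-view curves additionally use each
  view's own features.

## Expression-based features

From a precursor profile (sequence, dot-bracket, mature/star/loop
intervals in 1-based closed coordinates, read stacks, library size):

1. % mature-arm nucleotides paired in the dot-bracket;
2. paired-nucleotide count in the lower (basal) stem;
3. % reads inconsistent with Dicer processing;
4. % reads mapping to the loop;
5. % reads mapping to the mature arm;
6. % reads mapping to the star arm;
7. % reads consistent with Dicer processing;
8. total precursor reads per million library reads.

Conventions adopted where the feature definitions left room:

* a read stack belongs to the region it overlaps most (ties resolved
  mature > star > loop); stacks overlapping no region dilute the
  regional percentages, so f4+f5+f6 ≤ 100;
* **Dicer consistency**: a read is consistent iff its 5′ end lies
  within ±1 nt of the mature or star 5′ end (tolerance configurable);
  f3 and f7 are forced complementary (f3 + f7 = 100). Alternative
  definitions restrict the denominator to arm-assigned reads; that
  variant is not implemented;
* percentages are weighted by read counts, not distinct stack counts;
* the lower stem, when not annotated, is inferred as the two flanks
  basal to both arms (both strands); an annotated interval is used
  verbatim. If no flank exists, f2 = 0 with a warning.

## CFS feature selection

Subset merit is Hall's formula,
`merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`, with absolute Pearson
correlations (point-biserial against the 0/1 class). The search is
best-first forward selection with backtracking, stopping after 5
consecutive non-improving node expansions; ties break to the
lexicographically smallest name set, and constant columns are dropped
with a warning. **Limitation:** the stale cutoff makes the search a
heuristic; under strongly collinear feature sets it can terminate
before reaching the globally best subset (measured at roughly 1% of
arbitrary random correlation structures with ≤ 8 features; exhaustive
agreement was observed throughout for weakly correlated structures).
Raise `max_stale` to search harder.

## AUPRC

Step-wise average precision: rank by descending score (stable sort, so
ties keep input order), average precision-at-rank over the positives'
ranks. No PR-space interpolation, which is optimistic. The value is
invariant under strictly monotone score transforms; with tied scores
the documented stable-order rule applies and randomized tie orders move
the value only marginally on realistic holdouts. The paired
improvement t-test utility pairs repetitions (final vs initial
checkpoint within a repetition).

## Synthetic scenarios

`default_scenario()` is the package's self-contained study condition:
150 positives / 600 negatives (~1:4 imbalance, echoing curated
candidate sets; an 80/20 split leaves ≈120+/480− for training), a weak
sequence view (12 features, 4 informative, 0.8 sd separation) and a
stronger expression view (8 features, 4 informative, 1.4 sd), with
inter-view redundancy 0.2 through a shared latent axis. The
separations are fixed so the 10-label seed baseline lands well inside
(0.4, 0.8) mean AUPRC across dataset draws — clearly above the ~0.2
prevalence floor, with headroom left for both stages; this was
verified across independent dataset seeds. `strongly_separated_scenario()`
(3.0 sd in both views) is used where near-perfect pseudo-label
fidelity is the point under test.

Features are class-conditional Gaussians: real expression features are
bounded percentages, real sequence features are correlated in
structured ways, and real candidate sets carry homology between
samples. None of that is emulated, so green trend tests certify the
learning protocol's behaviour under its stated assumptions, not
real-data performance.

Toy precursor profiles are structurally valid hairpins (balanced
dot-bracket, disjoint arm/loop intervals) with read stacks placed on
the arms ("true-like") or diffusely ("false-like"); they exist to
drive the feature extractor and its I/O end to end.

## Numerical and reproducibility notes

* All randomness descends from one master seed via
  `numpy.random.SeedSequence` spawning: split, per-repetition streams,
  seed draws, forest random states. Reruns are byte-identical,
  including serialized TSVs (floats fixed at 6 decimals).
* Selection tie-breaks (equal scores, equal merits) resolve to the
  lexicographically smallest sample id / feature-name set, making every
  stage deterministic given its inputs.
* Degenerate situations are rules, not errors: exhausted unlabeled
  pools end a stage early with a logged notice; a singleton pool yields
  a one-sided selection; a single-class labeled pool is a hard error
  (the forest cannot be fit).
* Test and acceptance runs use 10–20 repetitions rather than the
  default 100; reported sds at these sizes are already small (< 0.05),
  which is what the repetition count needs to demonstrate.

## Known limitations

* Two views exactly; classical shared-pool co-training and >2 views
  are out of scope.
* No dynamic stopping criteria for either stage; horizons are fixed.
* The stand-in sequence extractor is minimal by design — externally
  computed sequence-feature catalogues plug in as ordinary feature
  tables.
* The simulated oracle requires withheld ground truth; in deployment
  mode queries become a pending-annotation worklist and learning
  pauses at those samples rather than growing the pool.
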