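# Methods

This note documents the models and procedures implemented in `trictl`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Coherence model and the mining algorithm

A time slice of the tensor is an objects × features matrix.  A bicluster
`(I, J)` of a slice is *ratio-coherent* at tolerance ε when, for every
ordered feature pair `(a, b)` in `J` (taken `a < b` in feature order), the
per-object ratios `v_b(x) / v_a(x)`, `x ∈ I`, span a range ≤ ε.  Ratio
range 0 captures exact constant and exact scaling patterns; small ε captures
their noisy versions.  A tricluster `(I, J, K)` requires `K` to be a run of
consecutive contexts and `(I, J)` to be ratio-coherent in every slice of
`K` — the temporal contiguity constraint is what makes the mined patterns
readable as disease-progression motifs.

Ratios need strictly positive values.  Clinical ordinal scores include 0,
so `MiningParams.shift` adds a constant (we use +1 for ALSFRS-R-derived
features) before mining; the shift is recorded in the output provenance.
Optional `transform="exp"` maps additive (shifting) patterns onto
constant-ratio ones, and `transform="log"` does the inverse, so all three
classical pattern families are reachable with the single ratio criterion.

The search:

1. **Multigraph** (per slice): one node per feature with ≥ `mx` observed
   objects; for each feature pair, the edges are the maximal object subsets
   with ratio range ≤ ε.  Because maximal subsets under a range constraint
   are intervals of the ratio-sorted objects, they are found by a two-pointer
   sweep; a pair may carry several edges.
2. **Maximal biclusters** (per slice): depth-first search over feature sets
   in canonical (ascending) order, carrying the family of maximal object
   sets valid for the current feature set; a feature is added by
   intersecting the family with the edges of every new pair.  Visited
   (objects, features) pairs are candidates; an exact containment filter
   keeps the maximal ones.  Object sets are represented as integer bitmasks
   throughout, which makes the intersections and subset tests cheap.
3. **Temporal merge**: candidate triclusters for a run are intersections of
   one bicluster per slice, grown incrementally (runs ending at context k
   extend runs ending at k−1).  States contained in another state of the
   same run are pruned — a contained state can never reach a maximal
   tricluster its container's line does not also reach; for speed the
   in-loop prune groups states by feature set, and the final exact
   containment filter establishes maximality.  Non-contiguous context sets
   are never formed.
4. **Overlap handling**: with η < 1, a tricluster whose cell overlap with a
   strictly larger one exceeds η of its own cells is deleted (overlap
   normalised by the smaller block, the usual pattern-mining convention);
   with γ < 1, two triclusters with union-normalised overlap > γ are
   replaced by the bounding block of their union if that block passes the
   coherence check.  Both passes iterate to a fixed point, visiting blocks
   largest-first with lexicographic ties.

With the δ caps disabled (the default) the composition is exhaustive: on
small tensors its output equals brute-force enumeration of all maximal
coherent contiguous triclusters (asserted in the test suite over random and
planted tensors up to 8×6×4).  Everything is deterministic — ties are
broken lexicographically on sorted index tuples and the miner contains no
randomness.

**δ caps.** `delta_x` caps each feature's value spread across the block's
objects, `delta_y` each object's spread across features, `delta_z` each
(object, feature) series' spread across contexts (applied per cell series,
not per aggregate).  They are implemented as post-filters on maximal
blocks: a block that fails a cap is dropped, and its capped *sub*-blocks are
not enumerated.  This keeps the search quasi-exhaustive rather than
exhaustive when caps are active; the caps default to disabled.

**Missing values.** Masked cells make an (object, feature) pair ineligible
in that slice; nothing is imputed inside the miner.  Last-observation-
carried-forward imputation exists separately (`impute_locf`) for the
baseline/classifier path, with training-fold statistics as the fallback for
leading missings.

## Virtual patterns and similarities

The virtual pattern of a tricluster (or of a single slice, after
*detaching*) has one entry per feature: the mean of the block's cells for
numeric and ordinal features, the mode for categorical ones.  The mode of
the full tricluster is recomputed over all its cells, not aggregated from
the slice modes, and ties are broken by first occurrence in object-then-
context scan order.  To compare an object with a 3D pattern its sub-array
is first reduced per feature over the pattern's contexts with the same
aggregators, making the Euclidean distance (VD) and Pearson correlation
(VC) dimensionally well-defined; for detached 2D patterns the single
matching slice is compared directly.  VC of a constant vector is undefined
and returns 0 with a logged warning.

Categorical entries are integer codes and contribute their raw code
difference to VD, consistent with the reference example this implementation
reproduces; for genuinely unordered categories with many levels this is a
known limitation (a denormalisation/one-hot step would be needed upstream).

Detached patterns are the default classifier features, one column per
`(tricluster, slice)` named `Tric_<id>_<position>` with position 0 the
earliest context.  For prognostic windows, patterns are anchored to the END
of each example's snapshot window (the most recent snapshots), since
recency carries the signal; an example too short to reach a pattern's slice
receives the degenerate value — the column's maximum observed distance, or
correlation 0 — and a log entry.

## Prognostic pipeline

*Snapshots* group each patient's evaluations by complete-linkage
agglomerative clustering on dates, stopping when the closest admissible
pair exceeds the 100-day cut (complete linkage guarantees the within-
snapshot span never exceeds the cut).  Two cannot-link constraints apply:
records of the same test never merge, and members must agree on every
endpoint's critical status.  The snapshot date is the median member date,
taking the earlier of the two middle dates for even groups.  When two
member records supply the same *feature*, the most recent value wins.

*Endpoints*: C1 Q12 ≤ 3 (non-invasive ventilation), C2 Q1 ≤ 1
(communication device), C3 Q3 ≤ 2 (gastrostomy), C4 Q5 ≤ 1 ∨ Q6 ≤ 1
(caregiver), C5 Q8 ≤ 1 (wheelchair).  The critical date is the first
evaluation meeting the rule, or a recorded event date when supplied.

*Evolution labeling* for horizon k (days, half-open interval `(i, i+k]`):
situation A — critical date within the window → Y; B — critical date beyond
it → N; C — never critical but some snapshot exists after `i+k` → N; D — no
status information after `i+k` → ineligible; E — the snapshot itself
critical → ineligible.  A snapshot dated on/after a recorded critical date
but not itself flagged is treated as situation E (the patient is already in
the critical period).  Labels are mutually exclusive and Y at horizon k
implies Y at any larger horizon while eligible.

*Windows*: eligible snapshots form sliding windows of length `min(L, nP)`
with stride 1 (so a patient with `nP ≥ L` snapshots contributes
`nP − L + 1` examples, and fewer snapshots yield a single shorter window);
the window's label is its last snapshot's.  Windows never contain a
snapshot dated on/after the critical date, by construction of eligibility.

*MITOS stage* counts compromised functional domains (movement Q8 ≤ 1 ∨
Q6 ≤ 1; swallowing Q3 ≤ 1; communicating Q1 ≤ 1 ∧ Q4 ≤ 1; breathing
Q10 ≤ 1 ∨ Q12 ≤ 2), with 5 denoting death.  The triggers live in
`mitos_rules.yaml` so clinical corrections need no code change.

## Rebalancing, cross-validation, evaluation

Inside each training fold only: if the majority class exceeds 2/3 of the
fold, it is randomly undersampled (seeded) to exactly twice the minority;
SMOTE then oversamples the minority to exact parity.  SMOTE is the standard
k-NN interpolation (k = 5, reduced when the minority is smaller), applied
in the transformed similarity space because rebalancing follows the
tricluster transformation in the workflow; it is implemented in-package as
a small seeded routine.  SMOTE also runs when undersampling is not
triggered — parity is always the endpoint.  A minority below 2 examples is
a hard error.

Cross-validation is 5 repeats × 10 folds, grouped by patient (patients are
atomic) and stratified on the label via scikit-learn's
`StratifiedGroupKFold`; when a class has fewer members than folds the
partitioner falls back to plain grouped folds with a warning.  Metrics per
fold: AUC (rank statistic), sensitivity and specificity at threshold 0.5,
reported in percent as mean ± sd over the 50 fold evaluations;
single-class folds are excluded from the AUC aggregate with a warning.

Classifiers are off-the-shelf with fixed seeds: Gaussian Naive Bayes,
RBF-kernel SVM (with probability calibration), Random Forest
(100 trees) and XGBoost (100 rounds).  Hyperparameter search over mining
grids scores each candidate by CV mean AUC of the mine → transform →
evaluate pipeline, breaks ties by fewer triclusters then lexicographic
parameters, scores a zero-tricluster candidate as AUC 50 with a warning,
and re-mines once with the winner.  Pattern relevance is reported as
permutation importance (mean AUC drop over 20 seeded shuffles per column),
keeping the `Tric_<id>_<position>` naming.

## Synthetic data

**Tensors.**  Background cells are i.i.d. uniform on a positive range, so
spurious exact ratio coherence has probability zero; planted blocks
(constant, scaling, or shifting, each with per-feature base values) are
overwritten with Gaussian observation noise.  Recovery is scored as
cell-level Jaccard with greedy best-match assignment between found and
planted sets.

**Cohorts.**  Each simulated patient draws a progressor class
(slow/neutral/fast, default mix 0.3/0.4/0.3 with rate multipliers
0.3/1.0/2.6), per-question latent baselines near the ALSFRS-R ceiling
(uniform 3.6–4.4, clipped at 4) and a latent linear decline
(0.12 points/question/month, per-question jitter ±35 %), observed at
irregular visits 60–120 days apart over ~3 years.  Scores are the
rounded-and-clipped latents, hence monotone non-increasing; FVC declines
linearly with Gaussian observation noise and is missing at 10 % of visits.
True endpoint-crossing dates are computed from the latent trajectory, not
the noisy observations, so labeling tests can separate observation error
from labeling error.  These defaults are a plausible specialist-clinic
follow-up; the generator targets structural realism (irregular visits,
monotone ordinal decline, controllable crossing times), *not* the marginal
statistics of any real cohort — passing tests show the machinery is
correct under the stated generative assumptions, not that a particular
clinical performance level would be attained on real data.

**End-to-end benchmark conditions.**  The discrimination check mines a
60-patient simulated cohort (endpoint C5, horizon 180 days, windows of
L = 3 snapshots) on five consolidated features (FVC, ALSFRS-R total,
bulbar and lower-limb sub-scores, MITOS) with ε = 0.05, m_x = 20 % of
examples, m_y = 3, m_z = 2, shift +1 and η = 0.75, then evaluates a Random
Forest on the detached-pattern distance matrix under the full 5×10 grouped
CV.  These problem sizes keep the whole suite comfortably interactive while
leaving hundreds of learning examples and dozens of patterns in play.

## Numerical and degenerate-case choices

- Ratio-range and δ-cap comparisons use a 1e-12 absolute slack to absorb
  floating-point round-off.
- All tie-breaks (mode, candidate ordering, pruning order, search ties) are
  deterministic; identical inputs and seeds reproduce identical outputs.
- `ratio_range` uses a stable argsort so tied ratios keep input order.
- Empty mining results are valid everywhere; an empty subspace has no
  virtual pattern (hard error), and a zero-variance vector has correlation
  0 by convention.
- Seeds derived for per-fold rebalancing are `seed·1000 + repeat·100 +
  fold`, keeping every stochastic step reproducible from one integer.

## Known limitations

- The ratio model needs strictly positive values; the shift constant is a
  modelling choice (recorded in provenance), and very large shifts flatten
  ratios, effectively loosening ε.
- With δ caps enabled the search is quasi-exhaustive (capped sub-blocks of
  failing maximal blocks are not enumerated).
- Maximal-pattern enumeration on heavily tied ordinal data can produce very
  large bicluster antichains; mining cost is controlled in practice by
  ε, `mx` and the feature-set size, and the merge keeps only maximal
  states, but worst-case complexity remains exponential — as for any exact
  miner of this family.
- Nominal categoricals contribute integer-code differences to the virtual
  distance (see above).
- The cohort generator does not simulate deaths, static covariates, or
  endpoint events recorded outside ALSFRS-R evaluations.
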