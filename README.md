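# trictl

Temporally constrained triclustering and tricluster-based prognostic
classification for longitudinal clinical data.

## What problem this solves

Specialist clinics follow chronic patients over years of irregular visits,
producing *three-way* data: patients × clinical features × time.  For
amyotrophic lateral sclerosis (ALS), the features are the twelve ALSFRS-R
question scores (each 0–4), the derived functional sub-scores, forced vital
capacity (FVC) and the MITOS disease stage, and the clinical question is
prognostic: *will this patient reach a critical endpoint — needing
non-invasive ventilation, an auxiliary communication device, a gastrostomy,
a caregiver, or a wheelchair — within the next k days?*

`trictl` implements a pipeline that answers this by mining **time-contiguous
triclusters**: subgroups of patients who share a coherent pattern on a
subset of features over a run of *consecutive* time points.  Each mined
tricluster becomes an interpretable classifier feature — a disease-progression
motif — rather than an opaque embedding.

## The method

**Mining.** A tricluster `(I, J, K)` is a set of objects `I`, features `J`
and consecutive contexts `K` such that, in every time slice, the per-object
value ratios of every feature pair in `J` span a range ≤ ε (which admits
constant and scaling patterns; an optional shift/log/exp transform extends
this to additive patterns).  The search has three phases: (1) per slice,
build a multigraph whose nodes are features and whose edges are maximal
ratio-coherent object subsets; (2) enumerate all maximal biclusters per
slice; (3) stack biclusters over consecutive contexts, keep maximal
triclusters, then optionally delete (η) or merge (γ) heavily overlapping
ones.  The nine hyperparameters are ε, the minimum sizes m<sub>x</sub>,
m<sub>y</sub>, m<sub>z</sub>, the per-dimension range caps δ<sup>x</sup>,
δ<sup>y</sup>, δ<sup>z</sup>, and the overlap thresholds η, γ.  The
enumeration is exhaustive (verified against brute force) when the δ caps are
disabled, and fully deterministic.

**Transformation.** A tricluster's *virtual pattern* ρ is its per-feature
prototype: the mean of the block's cells for numeric features, the mode for
categorical ones.  *Detaching* splits a tricluster into its per-context
slice patterns, named `Tric_<id>_<position>`.  An object is compared with a
pattern by the virtual distance `VD(p, ρ) = sqrt(Σ_e (p_e − ρ_e)²)` or the
virtual correlation (Pearson); the resulting example × pattern similarity
matrix is the feature space for any standard classifier.

**Prognostic pipeline.** Raw evaluation records are consolidated into
snapshots by constrained complete-linkage clustering of visit dates (100-day
cut; records of the same test, or disagreeing on an endpoint's critical
status, never merge).  Each snapshot is labeled for an (endpoint, k-days)
task: Evolution = Y if the critical date falls within `(i, i+k]` of the
snapshot date `i`, N if information beyond `i+k` rules it out, ineligible
otherwise.  Windows of `min(L, nP)` consecutive snapshots form the learning
examples.  Training folds are rebalanced (random undersampling of the
majority to 2/3 when it exceeds that share, then SMOTE to parity) inside a
5×10-fold patient-grouped stratified cross-validation; test folds are never
touched.

## Worked example

Plant a 12-patient × 4-feature × 3-context constant block in a 50×10×8
noise tensor, mine it back, and build the classifier features:

```python
import numpy as np
from trictl import (MiningParams, PlantedBlock, PlantedGroundTruth, plant_tensor,
                    tc_tricluster, detach, build_feature_matrix, match_triclusters)

blocks = [PlantedBlock(tuple(range(12)), (0, 1, 2, 3), (5, 6, 7), "constant", 2.0)]
truth = PlantedGroundTruth(blocks, noise_sd=0.01, seed=42)
data = plant_tensor((50, 10, 8), truth)

tris = tc_tricluster(data, MiningParams(epsilon=0.1, mx=8, my=3, mz=3))
t = tris[0]
print(f"objects={t.object_ids}")
print(f"features={t.feature_ids}, contexts={t.context_ids}")
print(f"recovery Jaccard = {match_triclusters(tris, blocks)[0]:.3f}")
for pattern, pos in detach(t, data, tricluster_id=0):
    print(f"Tric_0_{pos}: rho = {np.round(pattern.vector(), 3)}")
examples = [data.values[i].T for i in range(len(data.objects))]
fm = build_feature_matrix(examples, tris, data, mode="distance")
print(fm.data.round(3).head(4).to_string())
```

prints

```
objects=(0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)
features=(0, 1, 2, 3), contexts=(5, 6, 7)
recovery Jaccard = 1.000
Tric_0_0: rho = [1.626 2.022 1.943 1.659]
Tric_0_1: rho = [1.623 2.025 1.948 1.659]
Tric_0_2: rho = [1.622 2.027 1.949 1.661]
   Tric_0_0  Tric_0_1  Tric_0_2
0     0.034     0.016     0.023
1     0.017     0.017     0.020
2     0.007     0.023     0.008
3     0.021     0.024     0.026
```

The miner recovers exactly the planted patients/features/contexts (Jaccard
1.0); the three detached slice prototypes are nearly identical because the
planted pattern is constant in time; and the planted objects (rows 0–3
shown) sit at distance ≈ 0 from every slice pattern, which is what the
downstream classifier exploits.

The same flow is available from the shell:

```bash
trictl simulate cohort --seed 4 --out cohort/
trictl label --records cohort/records.csv --endpoint C5 --k 180 -L 3 --out examples.csv
trictl mine --data tensor.csv --manifest manifest.yaml --epsilon 0.05 \
       --mx 8 --my 3 --mz 2 --out triclusters.jsonl
trictl transform --triclusters triclusters.jsonl --data tensor.csv \
       --manifest manifest.yaml --mode distance --out features.csv
trictl train --features features.csv --labels labels.csv --clf rf --seed 1 --out report.json
```

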