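# lateralize

Machine-learning lateralization of temporal lobe epilepsy (TLE) from
resting-state fMRI. Determining whether the seizure focus lies in the left
or right temporal lobe is a key step in pre-surgical evaluation; this
package implements a complete, testable pipeline that predicts laterality
from resting-state connectivity features, exercisable end to end on
synthetic cohorts with planted lateralized effects — no imaging data
required.

## What it computes

From each subject's preprocessed 4D BOLD run (NIfTI), an integer-labelled
parcellation and a confound table, the pipeline builds a candidate feature
space spanning three levels of brain organisation:

* **Voxel level** — ALFF (summed spectral amplitude in 0.01–0.08 Hz), fALFF
  (ALFF over the full-spectrum amplitude) and ReHo (Kendall's coefficient
  of concordance *W* between a voxel and its 26 neighbours), each divided
  by its subject-wide mean.
* **Region pairs** — Fisher-z Pearson correlations *z* = atanh(*r*) between
  region-mean time courses after regressing out six motion parameters and
  the global/white-matter/CSF signals, pre-filtered by a one-sample
  *t*-test against zero on the training subjects of each fold.
* **Whole network** — binary graphs at correlation thresholds 0.05–0.30
  (step 0.05); six nodal metrics (degree, shortest path length, global and
  local efficiency, clustering coefficient, betweenness) and eleven global
  metrics including assortativity, transitivity and small-worldness
  σ = γ/λ against degree-preserving rewired null graphs. At 116 regions
  this yields 66 global and 4176 nodal candidates.

Classification is leave-one-patient-out: in each fold, features are ranked
per sub-category by mean random-forest Gini importance over repeated
forests, the per-category top-50 are pooled (≤ 300) and re-ranked, and the
shortest prefix minimising the forest's out-of-bag error is fed to a linear
SVM. Feature importance is aggregated across folds by rank scores (the top
of an *m*-feature run scores *m*, the last scores 1, normalized to unit
mass per run).

## Worked example

```python
from lateralize import LateralityModel, build_feature_table, demo_config, simulate_cohort

cfg = demo_config(seed=42)                      # 7 L / 5 R subjects, 12 regions
subjects, atlas = simulate_cohort(cfg.cohort)   # planted lateralized effects
table = build_feature_table(subjects, atlas, thresholds=cfg.thresholds,
                            n_null=cfg.n_null, seed=cfg.seed)
results = LateralityModel(table, cfg.classifier_config()).fit(seed=42)
print(results.summary())
```

prints:

```
TLE Laterality LOOCV Results
============================================
Subjects:               12
Candidate features:     3588
Correct rate:           11/12 = 91.67%
Sensitivity (L):        0.86
Specificity:            1.00
Selected per fold:      1, 1, 1, 2, 1, 2, 1, 1, 2, 1, 3, 1
--------------------------------------------
Sub-category importance (% of total mass):
  ALFF         30.6%
  fALFF        19.4%
  ReHo          6.9%
  FC            2.8%
  NMglobal     22.2%
  NMnodal      18.1%
============================================
```

The cohort carries three planted group differences (a ×2 amplitude region,
a high-coherence region and one coupled region pair); the nested LOOCV
recovers them — 11 of 12 patients correctly lateralized, mostly from one or
two selected features per fold — and the importance mass concentrates on
features tied to the planted regions. The same run is available from the
shell: `lateralize run-all --seed 42 --out results/demo`.

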