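# Methods

## Problem and model

Unilateral temporal lobe epilepsy alters resting-state brain activity at
three scales: locally (amplitude and neighbourhood coherence of the BOLD
signal), between regions (functional connectivity) and across the whole
network (graph topology). The package treats lateralization as a binary
supervised-learning problem over a candidate feature space that spans all
three scales, with feature selection nested inside a leave-one-patient-out
cross-validation (LOOCV) so that the held-out patient never influences any
data-dependent choice.

## Voxelwise metrics

All per-voxel processing starts from linear detrending (OLS removal of
intercept and slope). Band-pass filtering is an ideal frequency-domain
filter: FFT bins outside [0.01, 0.08] Hz (band edges inclusive, DC
excluded) are zeroed. Spectral amplitude is defined as the square root of
the periodogram power per bin, i.e. 2|X_k|/T; any constant factor cancels
in the later global-mean standardization.

* **ALFF** — sum of in-band amplitudes, computed on detrended, spatially
  smoothed, *unfiltered* data.
* **fALFF** — in-band amplitude sum divided by the amplitude sum over all
  non-DC bins, in [0, 1]; 0/0 is defined as 0.
* **ReHo** — Kendall's coefficient of concordance over the 27-voxel
  neighbourhood (K ≤ 27 after mask truncation at borders):
  W = 12 Σ_t (R_t − K(T+1)/2)² / (K²(T³ − T)), with per-voxel average
  ranks over time. Ties get average ranks; no tie-correction term is
  applied (ties are measure-zero for continuous data at T = 135). ReHo is
  computed on band-passed, *unsmoothed* data, and the resulting map is
  then smoothed. Voxels with K < 2 usable neighbours score 0.

Gaussian smoothing uses a separable kernel with σ = FWHM/(2√(2 ln 2)) per
axis in voxel units (default FWHM 4 mm) and nearest-neighbour edge
handling, so constant volumes are exactly invariant. Each of the three
maps is finally divided by its subject-specific in-mask mean (standardized
maps have in-mask mean 1).

The processing order — ALFF/fALFF before filtering, ReHo on unsmoothed
data — is fixed; whether ALFF/fALFF see smoothed data is a switch
(`smooth_before_spectral`, default on).

## Connectivity and graphs

Region-mean time courses are extracted from the labelled atlas, then each
column is replaced by its OLS residual against the confounds (six motion
parameters, global, white-matter and CSF means; an intercept is added if
absent and collinear columns are dropped with a warning). Connectivity is
Pearson correlation with Fisher's z; |r| is clipped at 1 − 10⁻⁷ so z stays
finite. The candidate filter keeps connections whose training-subject
z-values reject a two-sided one-sample t-test against 0 at α = 0.05
(configurable); it is applied *per fold*, on the eleven training subjects
only, to avoid leakage. The feature space uses all region pairs of the
atlas.

Graphs are built at correlation thresholds 0.05–0.30 in steps of 0.05:
an edge exists where tanh(z) > threshold (signed; negative correlations
never form edges — an absolute-value variant would be a one-line change in
`binarize`). Per threshold, six nodal metrics and eleven global metrics
are computed. Path lengths are BFS hop distances averaged over reachable
pairs only (isolated nodes score 0); efficiency handles disconnection via
1/∞ = 0; clustering is 2t/(k(k−1)) with 0 for degree < 2; local efficiency
is the global efficiency of the neighbour-induced subgraph; betweenness is
normalized shortest-path betweenness. Global metrics add Newman degree
assortativity (undefined for degree-regular edge sets), transitivity
(3·triangles/connected triples) and the small-world triple γ = C/⟨C_null⟩,
λ = L/⟨L_null⟩, σ = γ/λ. Null graphs are degree-preserving double-edge-swap
randomizations (10 swaps per edge, 100 nulls by default; both
configurable). Because nodal and global metric lists in the source
toolchains are open-ended, the sixth nodal metric and eleventh global
metric are taken as betweenness and its network mean, which reproduces the
candidate counts 6·R·6 (= 4176 at R = 116) and 11·6 = 66 exactly.
Metrics that are undefined on a given graph (e.g. γ on an edgeless graph)
are recorded as NaN and dropped per fold by the selection stage.

## Group comparison

The reference univariate analysis uses the two-sided Mann-Whitney U-test
(exact null distribution when n₁+n₂ ≤ 20 without ties — cheap at 7 vs 5 —
normal approximation with tie correction otherwise) at p < 0.01, followed
by cluster-extent correction: 6-connected components of at least 16 voxels
survive. A Monte Carlo estimator of the minimum extent is provided for
other grids: smooth Gaussian noise volumes are thresholded two-sided at
the voxel p, and the returned extent is the smallest s with
P(max cluster ≥ s) ≤ family α.

## Selection, classification, importance

Within each LOOCV fold: features of each sub-category (ALFF, fALFF, ReHo,
FC, NMglobal, NMnodal) are ranked by mean random-forest Gini importance
over repeated forests (default 500 trees, 50 repetitions seeded
seed+1..seed+50; zero-variance and NaN features are dropped first and
logged); the per-category top-50 are pooled (≤ 300) and re-ranked the same
way (repeated forests, for symmetry with stage one); prefixes of the
pooled ranking are grown one feature at a time, each scored by the
forest's out-of-bag error, and the *shortest* prefix attaining the global
minimum is selected ("minimum feature set" read literally; a flat trace
selects one feature). scikit-learn's normalized mean-decrease-in-impurity
importances are used; ranking is invariant to that normalization.

The classifier is a linear-kernel SVM (C = 1 by default; the cost is
unspecified upstream, so the LIBSVM default is kept). Features are
z-scored with training-fold statistics before the SVM — mixing counts,
ratios and z-values on one margin demands a common scale; the switch
`standardize` restores raw features. No class weighting is applied to the
7-vs-5 imbalance. Evaluation reports correct rate, sensitivity and
specificity with left TLE as the positive class.

Importance: in a run that selected m features, rank j scores m − j + 1,
normalized by m(m+1)/2 (ranks follow the pooled importance ordering, which
coincides with selection order since the selected set is a prefix of the
ranking). A feature accumulates its normalized scores additively over
runs, so total mass equals the number of runs and sub-category percentages
are taken against that mass.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the emulated acquisition scale: 135 volumes, TR 2.5 s, band-limited
(0.01–0.08 Hz) latent signals. Each atlas region r has a latent u_r
(band-passed white noise, unit variance); a voxel in r carries
amp_r·(√m_r·u_r + √(1−m_r)·ε_v) plus broadband measurement noise of sd
0.5, with voxel-specific band-limited noise ε_v and baseline mixing
m_r = 0.3. Planted effects, applied to the target group only, mirror the
three feature scales: amplitude factors multiply amp_r; coherence effects
raise m_r toward 1; coupling effects blend a shared latent into two
regions with weight δ, inducing inter-regional correlation ≈ δ. The
default strong preset — amplitude ×2.0 on one region, coherence 0.9 on
another, coupling 0.6 on one pair, all carried by the left group — was
fixed a priori from the effect kinds above. The toy atlas tiles the grid
with axis-aligned contiguous blocks of ≥ 27 voxels (a full ReHo
neighbourhood) and reserves the top grid slice as white-matter and CSF
compartments so nuisance regression is exercised end to end; motion
confounds are smooth random walks.

What the generator does *not* emulate: hemodynamic response shape,
cardiac/respiratory noise, scanner drift beyond a linear trend, anatomical
region shapes, or spatially structured noise. Passing recovery tests
therefore demonstrate that the pipeline's inference machinery is correct
and leakage-free under its own assumptions — not that the published
anatomical findings would replicate on clinical data.

Per-subject seeds derive from `SeedSequence(cohort_seed, spawn_key=(i,))`,
so cohorts are reproducible and subjects independent; all downstream
randomness (per-fold forests, rewiring nulls, SVM-free stages) flows from
named offsets of the run seed.

## Problem sizes used by the test suite

Unit and property tests run at desk scale (grids ≤ 24³, graphs ≤ 116
nodes). The end-to-end recovery checks use the demo configuration —
12 regions on a 12×12×8 grid, 7 L / 5 R subjects, forests of 20 trees with
2 repetitions and top-5 pooling, 6 rewiring nulls — over 20 replicate
effect cohorts and 20 null cohorts; at these sizes one full nested LOOCV
takes ~13 s. The selection-quality Monte Carlo tests use 200-tree forests
where ranking stability is the property under test. Statistical
calibration uses 10⁴ null replicates.

## Known limitations

* The exact Mann-Whitney path requires tie-free data; heavily tied inputs
  fall back to the approximate test even at small n.
* γ/λ estimates are noisy for very sparse graphs (few alternative
  wirings); they are NaN below one edge rather than extrapolated.
* OOB error at 11 training subjects is coarse (quantised in 1/11 steps),
  so the selected prefix length is variable across seeds — inherent to the
  procedure, visible in the per-fold feature counts.
* The per-fold candidate FC filter is one reading of an ambiguous
  protocol; filtering once on all subjects would leak test information and
  is deliberately not the default.
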