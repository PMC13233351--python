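# Methods

## Problem setting

BALF mNGS data are a mixture of microbial and host DNA sequenced shallowly
(single-end 50-bp scale, ~0.05–1× host coverage). Two feature families are
derived per sample: window-level host copy-number Z scores and
species-level microbial read counts. A binary classifier (malignant vs
non-malignant) is trained on high-quality labels, optionally extended with
pseudo-labeled weakly labeled samples, and evaluated on a held-out split.

## Sample QC

A sample enters CNV modeling only with ≥ 5 Mb of host-derived bases **and**
≥ 0.05× effective host-genome coverage (both inclusive). Below either
threshold the host count profile is too sparse for stable window
statistics.

## CNV feature derivation

1. **Tiling.** Non-overlapping fixed-size windows (default 1 Mb), 0-based
   half-open, last window of a chromosome may be short. GRCh37 chr1–22, X,
   Y yield 3,113 windows; reads are assigned by leftmost position (BED
   convention — the coordinate frame is a package choice, as is read
   assignment by leftmost base).
2. **Normalization.** Each sample is scaled so its total count over
   unmasked windows is 10⁶ (per-million scaling), removing library-size
   differences exactly: scaling a sample's raw counts by any c > 0 leaves
   all downstream features unchanged.
3. **GC/mappability correction.** Windows with mappability < 0.8 are
   masked outright rather than down-weighted (shallow counts in ambiguous
   regions are better discarded than re-scaled). Per sample, a LOESS-style
   local regression (span 0.3) of normalized coverage on window GC is fit
   over unmasked windows; each window is divided by the fitted value and
   the profile is rescaled to preserve its pre-correction median. This
   inverts smooth multiplicative GC bias of realistic amplitude (tens of
   percent); it is not designed for order-of-magnitude dropout curves.
4. **Log2 ratios.** `x_b = log2(sample_b / median_b)` against the per-window
   median of the corrected reference-panel profiles. Windows where the
   sample has zero coverage are masked for that sample, not clamped —
   a zero at ~1000 expected reads is missingness, not signal.
5. **Reference baseline and PCA denoising.** The baseline is fit only on
   designated non-malignant reference samples (≥ 2 accepted, < 30 warns;
   the library default mirrors a 200-sample panel) and then frozen. PCA is
   fit on the column-centered reference log2 matrix (missing entries
   imputed at the column mean). `k = "auto"` keeps components whose
   eigenvalue exceeds the mean eigenvalue (Kaiser-type rule), capped at
   10. Scoring subtracts each profile's projection onto the retained
   components — removing shared depth/batch structure while leaving
   isolated CNV segments (which are not a dominant reference-wide
   direction) essentially untouched.
6. **σ estimation.** With k > 0, σ_b is estimated from leave-one-out
   residuals: each reference sample is projected onto components refit
   from the other references. A full-fit residual SD would be biased low —
   the components partially chase the panel's own noise — which would
   systematically inflate the Z scores of held-out samples. The LOO
   estimate reproduces the situation of a test sample exactly; with k = 0
   the plain column SD is used. σ is floored at 1e-4 to keep degenerate
   windows finite.
7. **Z scores.** `Z_b = (x_b − μ_b)/σ_b`. Windows masked for a sample get
   Z = 0 ("no deviation"), a neutral imputation for tree models.
8. **Availability filter.** A window is retained iff its raw count is ≥ 1
   in at least 25% of samples (inclusive); retained windows are also
   intersected with the mappability mask. Availability means "≥ 1 read in
   that sample" — both definitions are package choices.

Under a no-CNV, no-batch simulation the held-out Z scores are calibrated:
|mean| < 0.05, SD within [0.9, 1.1], and P(|Z| > 3) near the Gaussian
0.0027 (the small residual excess reflects σ being estimated from a finite
panel, a t-like correction of order n_reference).

## Microbial features

Species-level clade read counts (rank "S" in Kraken2-style reports,
subspecies folded in). A species is *detected* in a sample only when its
count strictly exceeds 2 reads; it is *retained* as a feature only when
detected in ≥ 10% of samples (inclusive). Feature values are raw read
counts — no compositional normalization is applied, a documented
limitation. Shannon diversity uses natural log (values of 3–4 over
hundreds of species are on the nats scale); richness counts species above
a read floor. No pathogenicity or commensal stratification is applied.

## Classifiers

* **Gradient-boosted trees** (XGBoost, default): fixed refit uses 100
  rounds, max depth 6, learning rate 0.3, gamma 0, colsample 1.0,
  min_child_weight 1, subsample 1.0, single thread.
* **Random forest**: 500 trees, mtry = ⌊√p⌋ (50 at p = 2,523).
* **Binomial GLM**: maximum likelihood via a near-zero L2 ridge (C = 1e8)
  so the p ≫ n problem stays solvable; a loud warning marks the
  rank-deficient regime. Its weak performance on thousands of correlated
  windows is expected, and it is kept as the linear reference point.

Baseline development uses stratified five-fold CV with a fixed seed over a
small fixed grid per method (boosted trees: depth 3 vs 6; forest and GLM:
a single setting), selected by mean out-of-fold AUROC and refit on all
training data. A small fixed grid is deliberately chosen over a large
framework-default search: reproducibility of the harness matters more here
than exhaustive tuning. Extension retraining never repeats CV — it is a
deterministic fixed-parameter refit. No feature scaling is applied before
combining feature families (tree models are scale-free; the GLM is
documented as unscaled). The decision threshold for confusion metrics is
0.5 unless overridden.

## Pseudo-label extension

The baseline model scores every weakly labeled sample; samples predicted
malignant with probability **strictly** greater than the confidence
threshold (default 0.8; 0.7/0.8/0.9 compared by `threshold_sensitivity`)
are added to training as pseudo-positives. Predicted non-malignant weak
samples are discarded — never added as negatives — and high-quality labels
are never modified. One self-training pass only; iterating would compound
selection bias without a fresh validation signal.

## Evaluation

Sensitivity, specificity, accuracy, Youden = sens + spec − 1 (computed
exactly from unrounded rates), and tie-aware Mann–Whitney AUC (ties get
half credit). Confidence intervals are class-stratified bootstrap
percentile intervals (default 95%, 2,000 resamples, seeded): resampling
within each truth class keeps every resample's metrics defined. The
comparison harness emits one row per (method × feature type × strategy)
and treats any overlap between a model's training samples and the
evaluation set as a fatal error. Top features are ranked by each method's
native importance (gain / impurity decrease / |coefficient|); CNV feature
ids resolve to genomic intervals. For localizing a *segment* of correlated
windows, the forest's mtry-limited splits spread importance across the
segment, whereas boosted trees concentrate gain on one or two windows that
suffice to separate the classes — the forest is therefore the model used
in the localization analyses.

## Synthetic cohorts

The generator starts at per-window counts (no reads, no alignment) and
emulates: negative-binomial counts (size 1,000 by default; Poisson in the
limit) around 1,000 reads per window — the 0.05× QC floor at 50-bp reads —
times a lognormal library factor, a unimodal log-quadratic GC curve
centered at GC 0.45 (invertible by the LOESS correction), a low-rank
multiplicative batch term exp(A·F) that the PCA denoiser can remove, and
in malignant samples CNV segments whose expected coverage is multiplied by
`(1 − tf) + tf·cn/2`. Species counts have per-species random prevalence
and heavily overdispersed NB abundance (size 0.5); by default they are
label-independent, with an optional log-abundance shift in malignant
samples for power studies. Weak samples carry a hidden true status (the
biology generating their counts) plus a clinical flag flipped with
probability `weak_label_noise` — so pseudo-label precision is measurable.

What the simulator does **not** model: real genomic CNV hotspots,
contamination structure or taxon co-occurrence in the microbiome,
platform/batch idiosyncrasies beyond low-rank multiplicative factors, or
label noise in the high-quality set. Passing tests therefore demonstrate
the internal correctness and calibration of the pipeline under its own
generative assumptions, not clinical performance.

## Problem sizes and numerical choices

Simulation-backed checks use: null calibration, 200 reference + 100
held-out normals × 500 windows; planted-segment and pseudo-label studies,
260 labeled + 80 weak samples × 500 windows with one cn=4 segment of 20
windows at tumor fraction 0.4 and 500 reads/window; feature-type ordering,
240 labeled + 60 weak × 300 windows and 80 species with 4 segments × 20
windows at tumor fraction 0.4–0.8. These sizes give stable Monte-Carlo
behavior (tens of thousands of null window-values; Youden margins several
times their sampling noise) at desk-scale runtimes. Ties in CV model
selection go to the first grid entry; eigenvalues are clipped at zero when
the Gram-matrix route is used; all-zero samples are excluded from
normalization with a warning; constant scores yield AUC 0.5 with a
warning; all randomness flows from explicit integer seeds.

## Known limitations

Printed Youden values in tables elsewhere may disagree in the third
decimal with printed sensitivity/specificity when those were rounded
before differencing; this package always computes the identity from
unrounded values. Microbial counts are modeled raw (no compositional
treatment). The GLM is intentionally under-regularized. Segmentation /
discrete CNV calling is out of scope — window Z scores are used directly
as features.
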