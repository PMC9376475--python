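# Methods

This note documents the models, the default parameters and the numerical
choices behind `hypoxiquant`, and what the synthetic benchmark does and does
not demonstrate.

## Optics and stain separation

Brightfield absorption follows Beer–Lambert: per colour channel,
I = I₀·10^(−OD), and the optical densities of co-localized chromogens add.
All quantitative work therefore happens in OD space.

* **White point I₀** is estimated per tile as the 99th-percentile
  per-channel intensity among background-glass candidates: pixels with
  saturation < 0.1 and brightness > 0.5 of full scale.  If no pixel
  qualifies, the quantile is taken over the whole tile, floored at 1, and
  the result is flagged.  *Known limitation*: on tiles with very little
  glass (< ~1% of qualifying pixels, e.g. a solid-tissue field with no
  gland lumina) the percentile can land in faintly stained cytoplasm and
  bias all ODs; per-slide calibration, when available, can be passed in
  directly as a `WhitePoint`.
* **OD transform**: OD_c = −log₁₀(max(I_c, 1)/I₀_c), clamped to
  [0, od_max] with od_max = 3.0.  The floor at 1 intensity unit keeps fully
  absorbed pixels finite; it also means 8-bit input saturates at
  OD = log₁₀(I₀) ≈ 2.4, so the od_max clamp only binds for higher-range
  inputs.
* **Stain basis**: the published H-DAB absorption vectors
  hematoxylin = (0.650, 0.704, 0.286), DAB = (0.268, 0.570, 0.776)
  (normalized), with the residual direction their cross product.  The basis
  is config-overridable per slide; no automatic (Macenko-style) estimation
  is attempted.  Unmixing is the exact per-pixel 3×3 linear solve;
  hematoxylin and DAB concentrations are clamped at 0 from below, the
  residual keeps its sign as a diagnostic.

## Nucleus segmentation and cell-body simulation

Nuclei are chromatin, chromatin is hematoxylin: segmentation runs entirely
on the hematoxylin concentration channel.

* Threshold: Otsu over the nonzero signal, floored at 0.15 OD so a
  DAB-dominated tile cannot drag the threshold into noise.
* Cleanup: one-pixel binary opening.
* Splitting: watershed on the negated Euclidean distance transform.  The
  distance map is Gaussian-smoothed (σ = 1 px) before peak detection
  because elongated fibroblast nuclei otherwise produce a plateau of
  near-equal maxima along their ridge and over-split.  Markers are
  deterministic (raster-ordered peaks with a minimum separation derived
  from the minimum nucleus radius).
* Fragments below the minimum nucleus area are merged into the touching
  segment that shares the most boundary (smallest fragment first, lowest
  label on ties) rather than dropped; silently discarding them was measured
  to bias HP low by ~15% relative on synthetic tiles.
* Size filter: nuclei outside [8, 300] µm² are discarded.

Cell bodies are simulated by growing class-specific cytoplasm radii around
each nucleus: epithelial 4 µm, stromal (fibroblast) 2 µm,
inflammatory/other 1 µm, with a 40 µm² average-fibroblast footprint kept as
the cellular/acellular-stroma prior.  These values are explicit morphometric
stand-ins for PDAC, exposed in `SizingHeuristics` and parameterized by every
test; they shape the synthetic benchmark rather than claim a measured truth.
A pixel reached by several dilations joins the nearest nucleus (exact ties
to the lowest id), so cells are mutually disjoint and their union equals
the union of the individual dilations.  A uniform 2 µm expansion
(`expand_cytoplasm_generic`) reproduces the generic one-size-fits-all
cytoplasm simulation of tissue-level platforms for comparison runs.
Classification happens on nuclear segments *before* expansion so the radii
can be class-specific.

The region map is a strict partition: cell bodies paint epithelial /
cellular-stroma / other regions; the tissue left over is acellular stroma;
everything outside the tissue mask (total OD ≤ 0.06, after closing) is
background.

## Consensus annotation and cell typing

Two annotators' labels merge under the precedence
epithelial < stromal < inflammatory/other, with `unannotated` as the
identity: agreement keeps the label, a single annotation is adopted, an
epithelial/stromal mismatch resolves to stromal, and any inflammatory call
dominates.  The merge is symmetric and idempotent (it is a maximum), which
the tests verify by exhaustive enumeration of all 16 ordered pairs.  The
asymmetry is deliberate stringency: a cell is only called epithelial when
nothing argues otherwise.

The classifier is a pixel-wise random forest (200 trees, √p features per
split, seeded) over a versioned feature recipe.  The default recipe ("v1",
10 features) is raw hematoxylin and DAB OD, Gaussian-smoothed versions at
σ ∈ {1, 2, 4} px, and the gradient magnitude of each channel; recipe "v2"
appends the 3×3 local standard deviation of each channel.  Training samples
at most 100 pixels per nucleus (so large nuclei cannot dominate), balances
classes by downsampling, and caps each class at 20 000 pixels to bound fit
time.  Per-cell prediction is the majority over the nucleus' pixel votes,
with ties broken toward stromal (then inflammatory/other), mirroring the
consensus rule's reluctance to call epithelium.

Concordance is reported as reference-normalized percent agreement: of the
cells the reference calls class c, the share the prediction also calls c.
The reference is named in every output because the definition is
directional.

## Positivity and hypoxic percentage

A measured cell is pimonidazole positive iff

    mean_OD_DAB / (mean_OD_DAB + mean_OD_hema) > 0.5   and   mean_OD_DAB ≥ 0.1

with zero-total-OD cells negative.  The fraction uses the two specific
stains only (residual excluded), and the 0.1 floor is applied to the DAB
mean OD — it is the quantity asserting that stain is present at all; both
choices are config-exposed.

HP is **area-based with a single denominator**: the analyzed tumor area
(epithelial + cellular-stromal + acellular-stromal regions).  HP_epi and
HP_str are the positive epithelial / stromal cell areas over that common
denominator, and HP_wt ≡ HP_epi + HP_str is a derived property, so the
additivity identity holds exactly by construction — a per-compartment
denominator would violate it.  Acellular stroma is tumor tissue, so it sits
inside the denominator and outside every numerator; inflammatory/other
cells and their region are excluded from both.  Aggregation to section or
patient level is an analyzed-area-weighted mean, which is identical to
pooling the underlying pixels and preserves additivity.

## Variance components and reliability

Section-level HP is modelled as value_ps = μ + b_p + e_ps with independent
Gaussian components (two-level), or value_psr = μ + b_p + s_ps + e_psr with
sections nested in patients and ROIs in sections (three-level).  HP is
modelled on the raw percentage scale; no transform is applied by default.

* Estimation: REML via statsmodels `MixedLM` (nested variance components
  through `vc_formula`), L-BFGS, max 200 iterations.  Closed-form ANOVA
  method-of-moments estimators (with the standard unbalanced k₀ correction)
  are implemented independently and used as the cross-check; REML and MoM
  agree within 1% on balanced designs in the tests.  Negative MoM estimates
  truncate to zero with a warning.
* ICC₁ = σ²_patient / (σ²_patient + σ²_within), where σ²_within collects
  everything below the patient level.  The reliability of the mean of k
  sections follows the Spearman–Brown step-up
  ICC_k = k·ICC₁/(1+(k−1)·ICC₁), algebraically identical to
  σ²_patient/(σ²_patient + σ²_within/k); the constant 0.85
  (`HIGH_RELIABILITY_ICC`) marks conventional high reliability in reports.
* Spearman rank correlation (average ranks on ties) handles cross-measure
  concordance; constant vectors are rank-degenerate and reported as
  not-available.

The front end is a statsmodels-style pair: `HPVarianceModel` (built from a
long dataframe) whose `fit()` returns `HPVarianceResults` carrying the
components, fractions, ICC table, a text `summary()` and an ICC-vs-k plot.

## Synthetic data: what it emulates, and what it does not

The tissue generator renders a 512 × 384 µm ROI at 0.5 µm/px (the
annotation-field geometry the pipeline targets): round epithelial nuclei
(r = 3.2 µm) ringing gland lumina, sparse elongated fibroblast nuclei
(4.5 × 1.4 µm), clustered small inflammatory nuclei (r = 2 µm), with
per-class hematoxylin OD (0.65 / 0.45 / 0.95, jittered 5%) over a 0.08 OD
cytoplasm background.  Hypoxia is rendered as DAB OD decaying exponentially
(λ = 45 µm) from randomly placed line sources — "hypoxic cords" standing in
for the poorly perfused regions remote from vasculature — without modelling
oxygen physics.  True positivity applies the same rule the pipeline uses to
the noiseless per-cell mean ODs, and true HP integrates positive-cell area
over the rendered region map, so ground truth is consistent with the image
by construction.  An optional `target_hp_wt` bisects a global DAB amplitude
so the true positive-area fraction hits a requested value (monotone, hence
convergent; granularity limited by single-cell areas).  Composition is the
exact forward model the pipeline inverts (stain basis + inverse
Beer–Lambert against a fixed white point) plus Gaussian sensor noise
(σ = 1.5 intensity units).

What the generator does **not** emulate: necrosis, tissue folds, out-of-
focus regions, scanner stitching artifacts, stain-vector drift between
slides, nuclear texture, or partial-volume mixing at cell boundaries.
Passing the synthetic benchmark therefore shows that the pipeline's
geometry, unmixing, classification and bookkeeping are correct under its
own physical model — not that the defaults are tuned for any particular
scanner or staining protocol.

Simulated annotators flip each cell's label with a configured probability
to one of the other two classes uniformly.  The hierarchical HP-table
generator draws the nested random-effects model directly, clips to
[0, 100] and reports the clip count; recovery tests use configurations
where clipping is absent.

## Benchmark sizes and tolerances

The end-to-end benchmark (`hypoxiquant.benchmark.run_benchmark`) generates
50 ROIs at the default geometry, splits them 25/25 into training and
validation by a seeded permutation, trains the forest on consensus labels
from two 10%-error simulated annotators, and evaluates on the held-out
half.  At these settings the pooled per-cell agreement with ground truth is
≈ 99% and ~96% of validation ROIs recover HP within 2 percentage points;
the residual failures trace to the tile-level white-balance limitation
noted above.  Stochastic recovery tests assert within three analytic
standard errors of the estimator at the stated design size (or on a mean
over replicate seeds for unbiasedness), not within ad-hoc bands; all
randomness is seeded, and every generator is byte-deterministic per seed.

## Known limitations

* Tile-level white balance fails gracefully but inaccurately on glass-free
  tiles (see above).
* Geodesic restriction of cytoplasm growth is approximated by Euclidean
  distance intersected with the tissue mask; a thin tissue isthmus can
  therefore be crossed where a true geodesic dilation would not.
* Whole-slide (pyramidal) formats, stain-vector auto-estimation, necrosis
  detection and survival modelling are out of scope; ROI selection and
  necrosis exclusion are assumed to happen upstream.
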