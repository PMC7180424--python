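# Methods

## Model and procedure

The package implements a two-stage diagnostic pipeline for whole-slide images
of colorectal polyps.

**Patch stage.** A slide is decomposed by a sliding window into fixed
224×224-px patches (stride = patch size, i.e. non-overlapping; windows that
would extend past a box are dropped, not padded — this affects at most one
window row/column and keeps the count at the closed form
⌊(L−224)/224⌋+1 per axis). Each patch receives a probability vector over
five classes in the fixed order (TA, TVA, HP, SSA, NORM); hard labels are the
argmax with ties broken by that order. Physical scale: at a 0.25 µm/px 40×
scan, a 448×448 µm patch is 224 px only after 8× downsampling, hence the
`extraction_downsample` field of `PatchSpec` (default 8). Synthetic slides
are drawn at extraction resolution directly and use factor 1.

**Slide stage.** Patch-class counts drive a hierarchical rule: the slide is
adenomatous when adenomatous patches (TA+TVA) are at least as numerous as
serrated ones (HP+SSA); the tie goes to the adenomatous branch as the
clinically more consequential call. Within the winning branch a strict
fraction threshold subclassifies: villous fraction > θ_v → TVA (default
θ_v = 0.30), SSA fraction > θ_s → SSA (default θ_s = 0.015). NORM patches are
counted but excluded from the branch comparison and both fractions. The
fraction denominator is the winning branch's patch count (`"branch"` mode);
the source description of the rule does not name a denominator, and reading
"amount of villous tissue" as a within-lesion proportion is the most natural
interpretation — the alternative (`"all_polyp"`, dividing by all non-NORM
patches) is one config flag away and is exercised in tests. A slide with zero
polyp patches raises a "no lesion detected" error rather than guessing.

**Calibration.** (θ_v, θ_s) are chosen by exhaustive grid search on a
training cohort (default grids: θ_v 0–1 step 0.05; θ_s 0–0.10 step 0.005,
finer because the operating value is small), maximizing mean per-class
accuracy by default; ties break toward the lexicographically smallest pair,
which makes calibration deterministic. The full objective surface is
returned for inspection. Raising either threshold can only move diagnoses
toward the below-threshold class (TVA→TA, SSA→HP), a monotonicity property
the tests check over random count vectors.

## Reference patch classifier

The classifier contract is backend-agnostic: anything exposing
`predict_probs(patches) -> (n, 5)` row-stochastic matrix plugs in, including
large residual networks. The shipped reference backend is a compact
two-conv-block network written directly in numpy (forward and backward by
hand): block-mean 8× downsample of the 224-px patch to 28×28×3, two rounds of
3×3 valid convolution + ReLU + 2×2 max-pool (8 and 16 filters), then a linear
softmax head. Design intent: class evidence in the synthetic textures is a
color/low-frequency-structure statistic, so a small network trains to ≥0.95
held-out accuracy in well under a minute on one CPU — the separability
guarantee every end-to-end test rests on.

Training uses seeded SGD with momentum 0.9 on cross-entropy, He-normal
("MSRA") initialization by default, and the geometric learning-rate schedule
lr(e) = 0.001 · 0.9^(e−1) (1-based epochs). The schedule's decay bounds the
total step mass at 10× the initial rate times the batches per epoch, so very
small patch sets are update-starved; desk-scale runs use ≥150 patches/class.
Default 20 epochs (the full-scale schedule this mirrors ran 200). Standard
augmentation — rotations in {0°, 90°, 180°, 270°}, horizontal/vertical flips,
and brightness/contrast/saturation/hue jitter (half-ranges 0.1/0.1/0.1/0.05,
magnitudes our choice) — is applied per sample per epoch, on the downsampled
image for speed; disabling it makes training exactly reproducible patch-wise.
Ensembles average member softmax outputs with equal weights (renormalizing
only if numerically needed); how the original multi-depth ensemble combined
its members is not documented, so unweighted averaging is adopted as the
assumption.

## Synthetic data

The generator emulates the *statistical structure* of an annotated WSI
cohort, not histology. Each class gets a parametric procedural texture
(distinct base hue + periodic structure motif: round tubules for TA,
elongated fronds for TVA, sawtooth serration for HP, large dilated crypts for
SSA, faint stroma for NORM; additive Gaussian pixel noise sd 0.03). The
default recipes keep the mean inter-class distance of a fixed
texture-statistic vector (channel means, gradient energy, dominant FFT
period) above 3× the intra-class spread — property-tested, measured ≈ two
orders of magnitude above the bound.

Slides (default 2048×2048 px ≈ 9×9 patch grid) carry 4 lesion ROIs of 3–4
tiles per side placed on the 224-px grid, so planted villous/SSA area
fractions are realized exactly at patch granularity (tile-count rounding
error ≤ 0.02 at default sizes; the generator warns when a custom spec cannot
realize a fraction that tightly). Annotations merge same-labeled tile runs
into variable-width boxes and include the NORM background. Per-slide
fractions in image cohorts are drawn uniformly from ranges that straddle the
decision thresholds across classes while each class stays ≥0.05 clear of its
own boundary (TA 0–0.25, TVA 0.35–0.60, HP exactly 0, SSA 0.10–0.35): tile
granularity cannot represent a nonzero HP fraction below 0.015. For
calibration studies needing finer granularity, `sample_planted_counts` draws
count-level cohorts (400–800 polyp patches/slide) whose fractions straddle
the planted thresholds tightly on the correct side of the strict inequality;
grid search on these recovers (0.30, 0.015) exactly at the default grids.

Annotator panels draw each rater's label independently from the confusion
row of the slide's true class. The default symmetric per-annotator accuracy
0.8864 is chosen so the 5-rater panel's analytic mean pairwise Cohen κ under
a uniform class prior is 0.72, the substantial-agreement level reported by
expert gastrointestinal panels; `expected_pairwise_kappa` computes the
analytic value for any model and serves as the Monte-Carlo oracle.

What passing tests therefore show: the pipeline's *mechanics* — window
arithmetic, label bookkeeping, threshold calibration and recovery, the
statistics — are correct, and the stages compose end to end. What they do not
show: performance on real H&E tissue. The textures have no stain variation,
scanner artifacts, tissue folds, mixed or ambiguous morphology, or
inter-institution effects; annotator errors are independent across raters
and slides. Real-slide accuracy claims require real cohorts and a full-scale
backbone.

## Statistics

All reported percentages are rounded half away from zero to one decimal;
machine-readable outputs retain unrounded values. Choices where the
convention was open:

- **Mean metrics** are unweighted arithmetic means of the four per-class
  one-vs-rest values. A class absent from the truth yields a missing
  sensitivity (never 0), which propagates to a missing mean.
- **CIs** on mean proportions use the Wald binomial interval
  p ± 1.96·√(p(1−p)/n), clipped to [0, 100] in percent. Treating the mean
  accuracy as a single binomial proportion reproduces both published
  intervals (89.6–97.4 at n=157, 82.7–91.3 at n=238) to 0.1%, so the
  interval form is adopted as a reconstruction.
- **"t test for proportions"** is implemented as the pooled two-proportion
  z-test, the standard reading, which reproduces the published P = .90
  (external accuracy, 86.6% vs 87.0%, n=238 per arm); the unpooled variant
  is available via flag.
- **Cohen κ** uses the observed label vocabulary for chance agreement
  (equivalent to the full vocabulary, since absent labels contribute
  nothing), is defined as 1 when p_e = 1, and panel agreement is the mean
  over all C(5,2)=10 rater pairs with a normal-approximation CI on that
  mean (the original method is unstated).
- **Majority vote** ties are resolved by a designated reference annotator's
  label among the tied classes (falling back to fixed class order), and
  flagged; the tie policy for 5 raters over 4 classes is ours.
- Worked-example reproductions treat the published per-class table values as
  inputs. Two Mean entries (internal and external model specificity) land on
  exact half-unit ties of those rounded inputs (95.75, 91.65), so agreement
  there is within half a reporting unit rather than exact — the underlying
  unrounded per-class values evidently averaged just below the tie.

## Problem sizes and numerical notes

Desk-scale defaults: cohorts of 10 slides/class (2048² px), 200 balanced
patches/class, 20 training epochs, ~400-slide count-level calibration
cohorts, 2000-slide annotator panels. At these sizes the full test suite
runs in ~3 minutes and the acceptance script in ~3 minutes on one CPU.
Degenerate inputs are contracts, not crashes: empty prediction lists give
zero counts, boxes smaller than a patch give empty windows, single-class
training and zero-polyp slides raise errors. All randomness flows through
`numpy.random.default_rng`/`SeedSequence`; same seed + same inputs gives
bit-identical slides, models and reports.

## Known limitations

- The reference backend is intentionally small; it demonstrates the
  interface and the synthetic separability guarantee, not state-of-the-art
  patch classification.
- Tissue detection / background masking before windowing is out of scope
  (synthetic slides are fully tissue).
- Pyramid WSI formats (SVS/NDPI) are not read; slides are plain PNG/TIFF
  rasters at extraction resolution.
- Only the four common polyp classes are modeled; high-grade dysplasia,
  adenocarcinoma and rarer serrated variants are excluded.
- Inter-institution effects (stain/scanner variation, site-dependent rater
  behavior) are not simulated; the generator cannot reproduce the
  internal-vs-external generalization gap.
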