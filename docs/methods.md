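# Methods

## Model hierarchy

Both models share a feedforward S1 → C1 → S2 → C2 hierarchy emulating the
ventral visual pathway from V1 to anterior IT.

**Preprocessing.** Images are converted to a single luminance channel,
rescaled to [0, 1] and resized (bilinear) so the height is exactly 140
pixels with the aspect ratio preserved. All later geometry is expressed on
this canvas.

**S1 (simple cells).** A bank of Gabor kernels, 4 orientations × 16 odd
kernel sides from 7 to 37 px. Per side `s`, the envelope width is
`σ = 0.0036 s² + 0.35 s + 0.18`, the wavelength `λ = σ / 0.8`, the aspect
ratio γ = 0.3 — the standard published HMAX parameterization, adopted
because both models descend from that lineage. Kernels are zero-mean and
unit-L2-norm; support outside the inscribed circle is zeroed. The response
is the absolute normalized cross-correlation `|k·w| / ‖w‖` of the kernel
with each image window (valid positions only, no padding), clipped to
[0, 1]. This makes a uniform image respond exactly 0 and bounds every later
distance. Windows with zero norm respond 0. Orientation 0 denotes a
horizontal-bar detector (carrier varies vertically).

**C1 (complex cells).** The 16 sides pair into 8 scale bands. Within a
band the two scale maps are center-aligned and merged element-wise by max,
then max-pooled over square neighborhoods growing from 8 (band 1) to 22
(band 8) cells with stride equal to half the neighborhood; only fully
contained windows are kept. Coordinates are 0-based, row-major, top-left
origin throughout.

**S2/C2 (prototype tuning and global pooling).** A prototype is a
`side × side × 4` patch of C1 values, `side ∈ {4, 8, 12, 16, 20, 24}` grid
units. Its S2 response at a position is `exp(-d² / 2σ_s²)` with `d` the
Euclidean distance between the patch and the C1 window; C2 is the global
max over all positions of all bands the patch fits in, so an exact
embedded copy of a prototype always yields C2 = 1. We set
`σ_s² = k · side² · 4` (proportional to the patch element count, so tuning
sharpness is comparable across sizes) with default `k = 0.001`. The default
was calibrated on synthetic data so C2 values spread over (0, 1] rather
than saturating: under a global max over ~10³ windows even weakly matched
prototypes find a close window, and a soft tuning (k near 1) drives every
C2 to 1.0, destroying both classification signal and the vigilance scale
below. With k = 0.001, re-encoding an image against its own prototypes
gives exactly 1, other images of the same domain give top-5 matches around
0.90–0.96, and cross-domain images around 0.6–0.8.

## Dictionary construction

**HMAX (random).** `n_per_size` patches per size (default 250, the
configuration used throughout the classification grid) are cut at uniform
random (image, band, position) locations of the feature-learning set;
duplicates are allowed. Patches are stored per band but matched against
every band at test time; scale tolerance comes from the global max.

**Stable (ART-inspired).** Images are presented once each. The pool's C2
activity is the match signal: the mean of the top-P units (P = 5, ties
broken toward lower index) is compared with the vigilance ρ. On resonance
(match ≥ ρ) nothing changes; on mismatch, for each size one candidate is
cut at the position whose best S2 coverage by the stored same-size
prototypes is lowest (ties in band/row/column scan order), and admitted
only if its maximum Pearson correlation with stored same-size prototypes is
below the decorrelation bar τ. Up to 3 mismatch rounds per image, after
which the image is flagged in the learning trace. Prototypes are never
removed or modified. This is a functional implementation of the
match/reset contract; the continuous on-center off-surround dynamics that
motivate it are not simulated.

Defaults ρ = 0.99 and τ = 0.7 were chosen so that, on the synthetic sets,
typical novel images trigger learning while re-presented ones resonate
(the match scale is compressed near 1 by the global max — see the S2
calibration above), and so that the decorrelation bar genuinely enforces
dissimilarity rather than only rejecting near-duplicates: under
least-covered candidate selection candidates are maximally novel by
construction and a bar of 0.95 never binds. Near-constant patches
(centered RMS < 0.02) are treated as "empty": Pearson correlation between
near-constant vectors reflects pixel noise, not structure, so two empty
patches count as duplicates and an empty patch never correlates with a
structured one. Without this convention the learner admits unbounded
background-noise patches.

## Experiment harness

Face identification trains on views {0°, ±45°, ±90°} (3 expressions per
view → 15 images per identity) and tests on views {±22.5°, ±67.5°} (12
images per identity); view sets never mix. Expressions-per-train-view is a
parameter rather than a hard-coded count, so the train-set size derives
from the view scheme. Object categorization uses 30 train and 50 test
images per category, drawn without replacement; categories need ≥ 80
images. Defaults are 15 random runs for faces and 30 for objects. Feature
learning modes: *within* (the split's own training images), *between*
(freshly sampled disjoint identities/categories, resampled per run),
*natural* (a fixed generic pool; dictionary budget default 1000 patches
per size, ≈ 6000 total).

The classifier is a one-vs-rest linear SVM (C = 1) on features
standardized by train-set statistics. Per-size experiments learn an
independent dictionary per size; the optional combined result concatenates
per-size C2 blocks. Patch sizes are compared with two-sided Wilcoxon
rank-sum tests over per-run accuracies: exact enumeration for samples
smaller than 8 (falling back to the tie-corrected normal approximation when
ties are present), tie-corrected normal approximation otherwise;
significance is annotated at the 0.05 / 0.01 / 0.001 bands.

## Synthetic data

**Faces.** Each identity is a parametric configuration of brow, eye, nose
and mouth primitives inside a fixed head contour on a 140 × 112 canvas.
Identity is *configural*: feature positions are drawn per identity inside a
layout box whose extent is `identity_scale` (default 48 px ≈ 12 C1 units of
the finest band), while the local shapes of the features are shared by all
identities and perturbed only by expression (eye aperture, mouth width and
curvature). This places identity-diagnostic structure at the intermediate
spatial scale the analysis is about: a small patch sees an eye edge that
every identity possesses (and the global max erases its position), whereas
an intermediate patch spans several features and their identity-specific
arrangement. Shrinking `identity_scale` compresses the diagnostic
configuration into few C1 units and collapses the advantage of intermediate
patches (negative control). Yaw views apply horizontal compression by
cos(view) plus a nose-ward shift; the far eye is occluded at full profile.
Drawing primitives use super-Gaussian (flat-core, crisp-boundary) profiles
so that small C1 patches see generic oriented edges, as in photographs;
soft Gaussian ramps would make small patches artificially diverse.
Pixel noise is Gaussian (σ = 0.02 by default); raising it lowers accuracy.

**Objects.** Categories cycle through six shape families (grating disc,
blob constellation, concentric rings, bar fan, polygon contour,
checkerboard patch) with per-category drawn parameters; within-category
jitter moves position (± 8 px), scale (± 12 %), orientation (± 0.18 rad)
and texture phase. Families are visually distinct, making categorization
easy for any reasonable feature set — deliberately so, since the study's
contrast is that generic recognition does *not* depend on feature size or
class-specific learning.

**Natural pool.** 1/f-noise backgrounds composited with random oriented
bars, blobs and grating patches: generic oriented structure at all sizes,
no labels.

All generators are bit-deterministic given their seed; child seeds are
spawned per identity/category/image.

## Problem sizes in the shipped checks

The test suite and the reproduction script scale the study down so every
stage reruns from scratch in minutes: pools of 14 identities / 6 categories,
10 random runs per experiment, 75 patches per size for both within and
natural modes (equal budgets isolate the effect of feature *content* from
dictionary size), and a reduced 4-scale / 2-band front end in unit tests
where full-scale fidelity is not the point. The qualitative conclusions —
the intermediate-size advantage for faces, the asymmetric
within-minus-natural gap, the thin 4×4 census of the Stable learner — are
asserted on these sizes over ≥ 10 seeds or runs.

## Known limitations

* The faces are blob-and-contour renderings: no texture, hair, lighting or
  photographic background. Passing checks show the models behave as the
  theory predicts *when identity is configural at a controlled scale*; they
  do not certify performance on photographs.
* The view warp is a 1-D compression, not a 3-D rotation; extreme profiles
  (±90°) carry little identity information, which mirrors the difficulty of
  real profile views but is not a model of them.
* The ART learner implements the functional match/vigilance/reset contract,
  not the underlying neural dynamics; its defaults are calibrated to the
  C2 scale of this implementation and should be re-calibrated if the S2
  sharpness `k` is changed.
* Object categories being linearly separable at nearly 100 % accuracy means
  object-task comparisons have little headroom; this is intended (the
  contrast of interest is the face task) but makes object-side size effects
  unobservable here.
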