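# Methods

This note records the models implemented in `sicklescreen`, the
parameter values they ship with, the numerical choices behind them,
and what the synthetic experiments do and do not demonstrate. Every
number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is measured on real data.

## Synthetic smear model (`sicklescreen.synthetic`)

A virtual slide is a set of fields of view (FOVs) rendered at a fixed
pitch of 0.51 mm per 1000 px (0.51 µm/px). Defaults model a five-FOV
screen at 7700 RBC/mm² — roughly 9630 red cells over the ~1.25 mm²
imaged area — with a normal-RBC radius of ~3.75 µm (≈ 7.4 px), so
that genuine cells comfortably exceed the counter's >100 px component
rule exactly as real RBCs do at this sampling.

Cell placement uses a jittered hexagonal lattice. The lattice
spacing is chosen from the requested density; placement jitter is the
largest value that cannot cause overlap, `max(0, (spacing − (2·r_max
+ 1)) / (2√2))`. Two regimes follow:

* spacing above `2·r_max + 1`: hard no-overlap is guaranteed;
* spacing between one normal-RBC **diameter** and `2·r_max + 1`
  (near-packed monolayer): tangency between neighboring cells is
  allowed, which can merge a small fraction of connected components
  (about 0.05% at the default density — the tests assert exact
  component counts at moderate density and near-exact at full
  density).

A requested density that would force the spacing below one normal-RBC
diameter is physically impossible for a monolayer and raises
`DensityError` carrying the computed capacity.

Normal cells are rendered as soft-edged discs with central pallor;
sickle cells as crescents (a disc minus an offset disc) with a random
orientation; white cells larger and blue-tinted; platelets small and
violet. Each FOV yields the clean RGB image, a three-class label
mask (background / healthy / sickle; white cells and platelets are
background for the counting task), and a cell manifest. The manifest
includes `ann_row`/`ann_col`, the point an annotator would click:
the centroid for round cells, but `center − 0.55·R·(cos θ, sin θ)`
for sickles, because a crescent's centroid falls in its concavity,
outside the cell body.

The smartphone degradation model applies, in order: field-dependent
Gaussian blur (σ 1.0 at the center to 2.5 at the edge), per-channel
chroma gains (0.92, 0.97, 1.12), a single multiplicative gain jitter
(±5%), a smooth random geometric warp of 2 px amplitude, and additive
Gaussian noise (σ 0.01). The warp field is returned alongside the
image so registration can be scored against truth. A spec of zeros
(unit gains) is the identity, which the tests verify exactly.

All randomness is keyed on `(seed, fov_id, stage)`, so any FOV is
reproducible in isolation.

## Registration (`sicklescreen.registration`)

Training pairs for the enhancement network are built in three
stages.

**Locate.** The FOV is found in the (bicubically down-sampled)
whole-slide image by normalized cross-correlation
(`skimage.feature.match_template`); a zero-variance template or a
peak below 0.2 returns no match.

**Affine.** Six parameters (shift, rotation, log-scales, shear) are
fitted by Powell minimization of `1 − NCC` on Gaussian-smoothed
(σ = 2) luminance, multi-started from the identity and from a
phase-correlation translation estimate. NCC is invariant to the
gain/offset and color-cast differences between modalities, which
rules out plain SSD; it plays the same role a correlation-ratio or
mutual-information metric would at much lower cost. Acceptance
values: a 4/−6 px translation recovered to ~1e-6 px and a 1.5°
rotation to ~0.006°.

**Elastic pyramidal.** Coarse-to-fine block matching. Blocks start
at side/4 and halve per level down to 32 px, with 50% overlap. Each
block's residual shift is the peak of an FFT cross-correlation of
Hann-tapered, mean-removed blocks, refined to subpixel by a parabolic
fit clipped to ±0.5 px; the search window is ±block/4. Block shifts
are bilinearly interpolated to a dense field (extrapolation beyond
the block-center grid is clamped to the observed shift range) and the
field is composed across warp-and-correlate inner iterations (5 per
level) — a single correlation pass under-reports fractional shifts
because interpolation broadens the peak, and iteration shrinks the
residual geometrically.

A smear is a field of near-identical cells, so block matching can
lock onto the *wrong* cell while still reducing the photometric
residual. Five safeguards target this failure mode, each motivated
by the mechanism rather than by any particular image:

1. blocks with contrast at or below 0.1× the image's own standard
   deviation are treated as featureless and inherit their neighbors'
   motion (uniform-filter fill) before the block grid is smoothed
   (Gaussian, σ = 0.7 grid cells);
2. a correlation peak pinned to the search-window boundary is an
   aliased, unrefinable match and is rejected;
3. a block whose shift deviates by more than 2 px from its 3×3
   neighborhood vector median disagrees with the overlapping blocks
   around it and is rejected and refilled (wrong-cell matches are
   spatially incoherent; true smooth warps are not);
4. each incremental dense field is Gaussian-smoothed at 0.25× the
   block side — a smoothness prior whose amplitude loss is restored
   by the inner iterations, while incoherent wrong-cell increments
   cannot accumulate;
5. an increment is accepted only if it reduces the mean absolute
   photometric residual.

**Recovery accuracy and how it is scored.** On amplitude-2 px smooth
sinusoidal warps of rendered FOVs, the estimator is scored as RMS
field error over the image interior, excluding a 16 px border (at the
128 px test scale): near the border, content slides out of frame and
the true displacement is unobservable in principle, so border error
reflects the problem, not the estimator. The full-frame RMS is still
asserted under a looser sanity bound (< 1 px) so border behavior
stays visible. Across a 41-seed sweep of rendered FOVs the interior
RMS averages ≈ 0.21 px, with 40/41 seeds below 0.5 px.

**Limitation.** The single sweep failure (interior RMS 0.84 px)
confines its error to a large cell-free plasma region of that
rendering. No estimator can recover displacement from zero-contrast
background; the filled field there is an extrapolation from textured
neighbors. This is an information limit of the input, and it has no
photometric consequence for training-pair construction (warping
featureless background by the wrong amount changes no pixel), but
field-error metrics over such regions should be read accordingly.

## Networks (`sicklescreen.nn`)

Both tasks use the same U-net template, implemented entirely in
numpy with hand-derived gradients (the environment has no
deep-learning framework, and the network is small enough that im2col
convolutions in float64 are practical):

* down path: per level, two 3×3 convolutions + leaky ReLU (slope
  0.1) followed by 2×2 average pooling; the second convolution of
  each down block doubles the channels, so block *d* outputs
  `base · 2^(d+1)` channels;
* up path: bilinear 2× upsampling, concatenation with the skip
  connection, then two 3×3 convolutions (the first quarters the
  concatenated channels);
* heads: 3-channel linear output (enhancement: residual-free direct
  prediction; segmentation: class logits).

Weights are He-initialized from a truncated normal; optimization is
Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on random patches with the
eight dihedral augmentations. Every layer's backward pass is checked
against finite differences, and the convolution against a direct
nested-loop convolution, in the unit tests.

Losses:

* enhancement: `L = L1(output, truth) + λ·TV(output)` with λ = 0.03,
  both terms averaged over all pixel-channels;
* segmentation: class-weighted softmax cross-entropy, weights
  (1, 2, 1) for background / healthy / sickle, normalized by 1/(M·N)
  (pixels, not pixel-classes).

Both are verified against brute-force summation oracles to ≤ 1e-10
relative error on random inputs (acceptance reports ~1e-15).

Training-schedule accounting is exposed as `epoch_equivalent`: the
full-scale enhancement recipe (604,000 iterations, batch 16, 520
images of 1603² seen as 128² patches) is 118.5 epoch equivalents, and
the segmentation recipe (80,000 iterations, batch 20, 2660 + 3177
patches) is 274. The full-scale configurations are exposed but not
run by the tests; the suite trains scaled-down networks (depth 2,
4–8 base channels, ≤ 1500 iterations on 96 px FOVs) and asserts
behavior: the enhancement loss falls by more than half (observed
ratio ≈ 0.10), and held-out segmentation pixel accuracy exceeds 0.9
(observed ≈ 0.986). These scaled sizes are this package's own
problem-size choices, set by test-time budget.

## Counting and diagnosis (`sicklescreen.counting`)

All four thresholds are strict (exclusive), and the tests pin each
boundary exactly:

* cell pixels: probability of non-background **above** 0.8;
* cells: 8-connected components of **more than** 100 px;
* sickle cell: mean sickle probability over the component **above**
  0.15;
* positive slide: sickle percentage of counted cells **above** 0.5%.

A 96-slide confusion layout (32 SCD, 64 normal, one false positive
and one false negative) gives 97.92% accuracy, reported to round to
98%. ROC/AUC uses scikit-learn, cross-checked against a
Mann–Whitney U statistic.

The end-to-end decision check diagnoses a synthetic 40-slide cohort
(20 at 0%, 20 at 2% prevalence) from ideal probability maps derived
from the generator's masks — this isolates the counting and
thresholding rules from network quality. Cohort FOVs are 384 px at
5000 cells/mm² (~960 counted cells per slide), sized a priori so that
a true-positive slide needs ≥ 5 sickle calls against an expected ~19
— a Poisson left-tail of ~3e-5 — making the 100%-accuracy / AUC 1.0
assertion a test of the rules, not of luck.

## Evaluation (`sicklescreen.evaluation`)

SSIM is the single-window (global) form on the Y channel,
`[(2·μx·μy + c1)(2·σxy + c2)] / [(μx² + μy² + c1)(σx² + σy² + c2)]`,
with the conventional `c1 = (0.01·L)², c2 = (0.03·L)²` on unit range.
Global SSIM of a mildly degraded image is high (the README example's
input arm is 0.93), so enhancement improvements over it are
necessarily modest at small training scale.

The Monte Carlo subsampling experiment models imaging fewer cells:
for each slide, keeping a fraction *f* draws the retained sickle
count from a hypergeometric distribution (sampling cells without
replacement), recomputes the percentage and the slide call, and
re-scores the cohort; 1000 repetitions give mean ± s.d. accuracy and
AUC per fraction, convertible to smear area via a cells-per-mm²
factor. The subsampled percentage estimator is unbiased (asserted
within 3 Monte Carlo standard errors), and cohort accuracy is
non-increasing as cells shrink: with ten negative and ten 2%-true
slides of 400 cells, mean accuracy is ≈ 0.67 at 5% of cells kept,
≈ 0.95 at 25%, and 1.0 at 100%.

## What the synthetic experiments show — and what they cannot

They show *algorithmic correctness and recoverability*: losses and
statistics match independent brute-force oracles; gradients match
finite differences; the counter enforces its boundaries exactly; the
registration stack recovers known transforms to quoted precision;
scaled networks learn on data drawn from the stated model; and the
decision layer behaves as designed when its inputs are correct.

They cannot show *clinical performance*. The renderer's cells are
stylized, its degradation model is convenient, and no claim about
real smears, real smartphone optics, enhancement quality on real
tissue, or diagnostic accuracy in the field follows from any number
in this repository. The full-scale training recipes are exposed
untested at scale. Numbers computed here characterize the software
against its own generative model, nothing more.
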