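# Methods

This note records the models implemented in `motioniq`, the defaults and
why they were chosen, the numerical decisions, and the limits of what the
synthetic experiments can show.

## Slice-wise evaluation and the pre-processing grid

All metrics are computed on 2D slices along the acquisition slice axis and
reduced across slices; there are no volumetric 3D windows. Only slices
whose brain-mask fraction is at least `min_brain_fraction` (default 0.1)
enter the evaluation, which removes unstable peripheral slices. The
reduction is either the mean or the *worst* slice — the minimum for
higher-is-better metrics and the maximum for lower-is-better ones —
mirroring how readers judge a volume by its most degraded slice.

Three pre-processing axes are treated as independent:

* **Masking.** `none` evaluates the full matrix; `multiply` zeroes the
  background (metrics still see the full matrix, including the zeroed
  region and the brain/background boundary it creates); `mask` restricts
  the evaluation domain to in-mask pixels. FSIM and VIF are defined through
  neighbourhood filtering of the whole matrix and therefore reject the
  `mask` domain.
* **Normalization**, always volume-wise (never per slice): `none`,
  `minmax` (min→0, max→1), `meanstd` (subtract mean, divide by standard
  deviation), and `percentile` (1st percentile→0, 99.9th→1, linear
  interpolation on the full intensity vector, clipped to [0, 1]). Clipping
  is not forced by the mapping's definition but guarantees the [0, 1] input
  range FSIM and VIF require. Percentile normalization is the robust
  option: a handful of extreme-valued voxels move the min-max mapping
  arbitrarily but barely move the 99.9th percentile.
* **Ordering.** Normalization statistics are computed on the volume as
  presented, *before* mask multiplication, so the four normalizations mean
  the same thing in every mask mode; `preprocess_volume(...,
  mask_before_norm=True)` switches to the alternative ordering.

Percentile idempotence is approximate, not exact: after mapping and
clipping, the 1st percentile of the result sits one inter-voxel spacing
above zero, so a second application shifts values by order 1e-4 on typical
volumes.

## Metrics

* **SSIM** uses an 11×11 Gaussian window (σ = 1.5), K1 = 0.01, K2 = 0.03,
  filtered moments (not sample covariance), and edge-padded filtering with
  the window-radius border excluded from the average. The dynamic range L
  defaults to 1 for unit-range inputs and to the reference's max−min
  otherwise. A `uniform_7` window is available as an option.
* **PSNR** takes the peak on the *reference*, per slice (peak and MSE are
  computed on the same evaluation domain). Identical inputs yield a +inf
  sentinel that is excluded from correlations downstream.
* **FSIM** combines phase-congruency similarity (stabiliser T1 = 0.85) and
  Scharr gradient-magnitude similarity (T2 = 160), weighted by the
  pointwise maximum phase congruency. Phase congruency uses a log-Gabor
  bank with 4 scales × 4 orientations (minimum wavelength 6, scale factor
  2, σ_onf = 0.55), a median-based Rayleigh noise floor (k = 2) and a
  frequency-spread sigmoid weight. The constants are calibrated for [0,255]
  intensities; unit-range inputs are mapped onto that range internally, and
  anything outside [0,1] ∪ [0,255] is rejected rather than rescaled. Images
  whose smaller dimension is much larger than 256 pixels are mean-pooled
  toward the calibration scale; 64–128 voxel MR slices pass unchanged.
* **VIF** is the pixel-domain variant (VIFp): a Gaussian-scale-mixture
  source model and a gain-plus-additive-noise channel, evaluated with
  multi-scale Gaussian windows over four dyadic scales, visual-noise
  variance 2 in [0,255] units. Pixels where the reference carries no local
  variance are excluded from both the numerator and denominator sums, which
  also makes identical inputs evaluate to exactly 1. The variant is
  recorded in the metric's spec. The pixel-domain form was chosen over the
  steerable-pyramid form for dependency-light reproducibility.
* **Gradients** for the reference-free metrics are centred finite
  differences in the interior and one-sided at the borders. Under the
  `mask` domain the gradients are computed on the full slice first and
  masked afterwards, so the domain boundary injects no artificial edges;
  under `multiply` the gradients see the zeroed background by design (that
  is precisely what distinguishes the two modes).
* **AES** detects edges with a Canny detector (Gaussian σ = 2, hysteresis
  thresholds at the 70th/90th quantiles of the smoothed gradient
  magnitude). The quantiles are computed over *positive* gradient pixels:
  on background-zeroed images the majority of pixels have exactly zero
  gradient and raw quantiles collapse. Slices without detected edges (or
  without any gradient, for NGS) report a missing value and drop from the
  reduction. Detector parameters are exposed in the function signature.
* **IE/GE** use the natural logarithm (values in nats) and the convention
  0·ln 0 = 0. IE is computed on the intensities as presented by the
  pipeline; when a normalization has produced negative values the energy
  normalisation uses |x|. All-zero domains raise a degenerate-input error.

## Agreement statistics

Observer scores are 1–5 Likert values (5 = artifact-free). The per-volume
summary is a weighted mean with weight 2 for radiologists and 1 for
radiographers; missing raters drop from numerator and denominator alike.
Inter-rater reliability is Krippendorff's alpha in the coincidence-matrix
formulation; the level of measurement defaults to *ordinal* (appropriate
for Likert data — the interval variant differs numerically and is recorded
in the report header when selected). Metric–observer association is the
Spearman rank correlation (Pearson on mid-ranks). Its two-sided p-value is
exact by full permutation enumeration for n ≤ 8, a seeded Monte-Carlo
permutation estimate (10 000 resamples, default seed 20250610) for
8 < n ≤ 20, and the t-distribution approximation for larger n. No
multiplicity correction is applied; the significance filter simply masks
cells with p ≥ 0.05. Metric ranking uses |ρ| (signs are reported raw —
lower-is-better metrics correlate negatively), with average ranks for ties
and the median taken across sequences.

Volumes whose metric value is undefined (+inf PSNR, AES without edges) are
dropped pairwise from that metric's correlation and the drop is logged.
Sequences are analysed independently; no pooling across contrasts.

## Synthetic study

The generator's job is to reproduce the *statistical structure* of a
motion-artifact reader study, not MR physics. A subject is a nested-
ellipsoid head (scalp, skull, CSF, a brain with a subarachnoid CSF rim,
grey/white matter, deep nuclei and ventricles whose sizes vary strongly
between subjects), with a coarse multiplicative texture and a fine additive
texture (correlation length ≈ 0.7 voxel) standing in for gyral and vascular
detail — the high-frequency content that motion blur destroys. The brain
mask includes the CSF rim, as skull-stripped masks do, so the
mask-multiplication boundary falls on dark CSF. The brain fills well under
40% of the 64³ field of view (3 mm voxels), so background dominates the
image as in real brain MR.

Motion corruption is segment-wise rigid k-space compositing: the
phase-encode axis (linear ordering, centre at line n/2) splits into 8
segments; per segment the object is rigidly transformed (trilinear
interpolation, rotation about the centre, zero padding) and contributes its
own lines of the 3D Fourier transform. Trajectories are random walks
recentred on the k-space-centre segment — the corrupted volume stays
co-registered with its reference, as in a registered study — and scaled so
that the segment-weighted mean displacement (counting a rotation θ as
r_eff·θ with r_eff = 64 mm) equals the requested severity in mm. Because
the transform is trilinear, sub-voxel translations low-pass the image
slightly; spectral energy conservation holds exactly only for whole-voxel
translations.

The default study is 22 subjects × (1 reference + 3 degraded volumes) with
an instructed severity ladder of 1.5 / 3.5 / 8 mm (±30% per-subject
jitter), matching the scale of instructed head nodding. Every acquisition,
references included, additionally carries:

* involuntary physiological motion (0.2–0.8 mm), so reference backgrounds
  contain their own ghosting;
* a pulsatile ghost: a half-FOV replica of the bright non-brain head
  tissue (the classic fat/flow ghost source) with random amplitude
  (0.05–0.25) and random phase-encode smear;
* up to two textured wrap-around bands at the FOV edges (aliasing of
  tissue outside the FOV), overlaid so intensities stay tissue-bounded and
  hard-limited to the outer 8 voxels so they never reach the brain;
* a smooth coil-loading modulation of the scalp brightness (gain 0.7–1.3
  per positioning);
* Rician noise applied *after* corruption and ghosting — thermal noise
  enters the receive chain, so motion must not smooth it — with a
  per-acquisition level of 0.4–0.7% of white matter.

These nuisance channels share a purpose: they put realistic
severity-independent variation into the image background, which is what
makes evaluating metrics without a brain mask genuinely worse rather than
trivially equivalent.

Raters: two radiologists and two radiographers score a latent quality
5 − a·severity (a calibrated so the worst volume lands near score 1), plus
a per-rater bias (SD 0.2) and noise (SD 0.3, radiographers ×1.6), rounded
and clipped to 1–5. All randomness flows from one master seed via
`numpy.random.SeedSequence` spawning; a study is bit-reproducible.

`inject_outliers` replaces a configurable voxel fraction (default 0.1%)
with random multiples (10–100×) of the volume maximum — the scenario that
derails min-max normalization while the percentile mapping clips it away.

## What the synthetic experiments do and do not show

On the default study the pipeline reproduces the qualitative structure a
real reader study exhibits: reference-based metrics correlate strongly
(|ρ| ≈ 0.9) with observer scores; AES is clearly the best reference-free
metric; percentile normalization is robust to outliers where min-max
collapses; and dropping the brain mask weakens most correlations.

Two caveats are intrinsic to a desk-scale simulation with a single rigid
severity parameter and should be kept in mind:

* **Tenengrad at the worst slice.** The minimum-TG slice is the peripheral
  slice just above the 10% brain-fraction threshold; there, gradient energy
  lost to blur is largely offset by motion-ghost energy flowing into the
  nearly empty mask region, so worst-slice TG is nearly flat in severity at
  this resolution. On real ~1 mm brains the fine cortical gradient content
  makes TG much more blur-responsive. Conclusions about TG's rank among
  reference-free metrics therefore do not transfer from this phantom world
  to real data.
* **Scale-invariant metrics without a mask.** With a single severity
  driving the whole volume, the fraction of image energy ghosted into the
  background is itself a clean severity readout, and distribution-shape
  metrics (NGS, IE, GE) can exploit it despite the injected background
  nuisances. In real data, background content is far less informative. The
  no-mask degradation is therefore reproduced for the reference-based
  metrics and AES/TG, but not reliably for the shape-based ones.

Other non-goals: no relaxation/spoiling or coil-combination modelling, no
through-plane motion for 2D multislice, no prospective-correction
simulation, no skull-stripping or registration (volumes and masks are
aligned by construction; real inputs must arrive co-registered).

## Problem sizes

Tests and the acceptance script use the study sizes stated above: 64³
phantoms for the default study and the severity ladder, 32–48³ phantoms for
unit-level checks. These sizes keep a full grid evaluation of all nine
metrics over 88 volumes in the minutes range on a single CPU while
preserving the statistical structure of interest.
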