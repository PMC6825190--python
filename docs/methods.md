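# Methods

This note documents the models implemented in `oralpdt`, the defaults and
why they were chosen, the numerical details that affect results, and what
the synthetic-data validation does and does not demonstrate.

## Synthetic endoscope video

The generator emulates the statistical structure of an intraoral endoscope
recording of a fiducial ink mark, not its photometric realism.

**Motion model.** The true marker centre follows

    p(t) = p0 + r·t + ε(t) + Σ_e s_e · (A_h, A_v) · w_e(t)

with baseline `p0`, constant drift rate `r` (px/frame), isotropic Gaussian
jitter `ε(t)` with per-frame SD `jitter_sd`, and sporadic "swallow"
excursions: raised-cosine pulses `w_e` of finite support
(`swallow_duration` frames, default 20 ≈ 1.3 s) whose start frames form a
discretised Poisson process with `swallow_rate` events/minute (default 1).
Each event carries one random sign `s_e` shared by both axes — the cheek
moves as a unit — with horizontal peak amplitude `A_h` (default 30 px)
twice the vertical `A_v` (default 15 px), reflecting that swallowing moves
the cheek musculature predominantly horizontally. Because the excursion is
always proportional to `(A_h, A_v)`, the ratio of horizontal to vertical
excursion ranges equals `A_h/A_v` exactly in the jitter-free limit; with
jitter it converges there as events accumulate.

The jitter is white (i.i.d. per frame). Real tissue motion is temporally
correlated, so a real recording with the same per-frame SD shows a smaller
displacement *range* over long windows than the white-noise model does;
range-based comparisons between the two regimes are therefore made at
matched SD, not matched range.

**Scene and rendering.** Frames are 640×480 RGB at 15 frames/s (the
endoscope product used clinically does not state its resolution or rate;
both are configurable). Three color classes: a blue-black elliptical ink
mark (default diameter 20 px, color (30, 30, 120)), pink mucosa
(225, 160, 160), and a white applicator border band (245, 245, 245),
followed by optional radial vignetting and i.i.d. Gaussian color noise
(default SD 4, clipped to [0, 255]). Colors, sizes and noise are
configurable; defaults were set once for realistic contrast. Ellipse
rasterisation includes boundary lattice points (an ε-inflated radius), so
pixel counts track the continuous area to a few percent at default sizes.
One integer seed drives everything through split numpy streams (0 = motion,
1 = rendering, 2 = fluorescence); identical parameters give bit-identical
output.

**Synthetic fluorescence pairs.** The pre image is a dim tissue background
(intensity 40/255) with a brighter ellipse (180/255) for the PpIX-rich
lesion; the post image multiplies everything inside a larger, concentric
bleached ellipse by `1 − drop_fraction` (default 0.5). The bleached mask is
unioned with the lesion mask so containment holds by construction for any
aspect ratios. A single Gaussian noise field (SD 3) is added to *both*
images: it models fixed-pattern tissue texture, which dominates
frame-to-frame variation in such photographs, and makes a zero drop
fraction yield bit-identical images. Consequence: pre/post noise is
perfectly correlated, which slightly flatters change detection relative to
independent shot noise; the 5 % recovery margins hold with independent
noise of this magnitude as well, but that regime is not what is generated.

## Marker tracking

Per frame, pixels are clustered in raw RGB (no color-space conversion —
the similarity judgement is defined on red, green and blue values) by
Lloyd's algorithm with k = 3, the number of scene classes (ink mark,
tissue, applicator). The iteration runs on the frame's *unique* RGB triples
weighted by their pixel counts, which is algebraically identical to Lloyd
on the full pixel multiset and ~30× faster on quantised images; the
iteration itself is scikit-learn's `KMeans` (weighted, single init,
`algorithm="lloyd"`). Final cluster means and inertia are recomputed
exactly from the converged labels, and clusters are renumbered in
decreasing size order so labels are reproducible.

**Initialisation.** Initial centers are the frame's dominant color modes: a
coarse 3D color histogram (32 levels/channel) is peak-picked greedily with
non-maximum suppression of each peak's 3×3×3 bin neighbourhood (a noisy
color class straddling a bin boundary yields one peak, not two); if fewer
than k separated modes exist, remaining centers are drawn by greedy
k-means++ (16 candidates per step, keeping the candidate that most reduces
the potential) from the configured seed. Pure sampled seedings —
including greedy k-means++ — were found to strand Lloyd in a local optimum
that splits the dominant tissue cluster instead of isolating the ink mark,
which occupies only ~0.1 % of the pixels; uint8 clipping aggravates this by
concentrating a saturated atom at (255, 255, 255) beside any bright
applicator color. Mode seeding gives each color class a center before any
center is spent on within-class structure. Everything remains a pure
function of (frame, k, seed).

**Cluster selection and centroid.** The reference color is the per-channel
mean over a user-drawn ROI on the first frame — in practice a tight
rectangle around the ink mark, so a minority of background pixels in the
ROI only displaces the reference slightly. The non-empty cluster with
minimal Euclidean RGB distance to the reference is selected (ties to the
larger cluster); its largest 4-connected component is kept (one mark, one
region) and the unweighted pixel centroid taken at sub-pixel precision,
0-based, x = column rightwards, y = row downwards. A frame is invalid when
the best distance exceeds `max_color_distance` (default 100 — far below
the ≥ 180 separation between the default scene classes, far above the
within-cluster scatter) or the component is empty; invalid frames carry NaN
centroids and are excluded downstream, never interpolated. Tracking aborts
only when more than half the analysed frames are invalid. Per-frame k-means
seeds are derived deterministically from the configured seed, and each
frame is clustered independently — no warm start, no temporal model, no
spatial preprocessing.

## Stability statistics

Pixel→mm calibration uses the known physical size of the ink mark
(`pixels_per_mm = extent_px / diameter_mm`); no other calibration source is
assumed, and a supplied scale can be passed directly. Displacements are
referenced to the mean centroid over valid frames (displacement plots are
then centred at zero; first-frame referencing is available). Per subject,
"range" is max − min of the displacement component — the natural reading
of staying "within a range" — with peak-|deviation| selectable; SDs use
the n − 1 denominator throughout. Cohort summaries report mean ± sample SD
across subjects and Tukey boxplot statistics: quartiles by linear
interpolation, whiskers at the most extreme values within 1.5 × IQR of the
quartiles, values beyond listed as outliers. Frames beyond the Tukey fences
on either axis (swallows, jaw adjustments) are reported per subject but not
removed from the statistics.

## Photobleaching quantification

Color photographs are reduced to the red channel by default (PpIX emits in
the red); the channel is configurable. The lesion mask is Otsu's threshold
on the pre image — scale-invariant, no tuned threshold — followed by
largest-4-connected-component retention and hole filling. The bleached mask
collects pixels whose relative drop `(pre − post)/pre` is at least
`drop_fraction` (default 0.3, comfortably below the ~0.5 drop a full
treatment produces and above background fluctuation), excluding pixels
whose pre intensity lies below the 10th percentile of the pre image (near-
zero pixels carry no bleaching information), again keeping the largest
component with holes filled. Hole filling matters: the intensity floor
randomly punches out ~10 % of the dim pixels *inside* the bleached field,
and without filling, areas are biased low by the same fraction. Pairs are
assumed registered; an optional rigid-translation registration by phase
cross-correlation is provided for pairs with camera or patient motion.

Areas are pixel counts divided by `pixels_per_cm²`. The packaged pilot-
cohort table lists, per patient, the lesion area and the *photobleached
area itself* (not the excess); the margin-coverage statistic is the mean ±
sample SD of the per-patient difference, 3.71 ± 1.53 cm² for the five
patients, with every difference positive (full margin coverage). Dosimetry
helpers are unit conversions only: 100 J/cm² over 35 min ⇒ 47.6 mW/cm².
The clinical segmentation procedure behind the cohort's published areas
(channel, threshold, calibration) is not recorded anywhere, so only the
table arithmetic — not the image-processing route to it — is exactly
reproducible for that cohort.

## Comfort survey

Scores are validated as integers in [1, 5], one response per (subject,
position, question). Summaries report mean, sample SD (n − 1), per-level
counts and the number of score-5 ("no tolerance") responses. The n − 1
denominator is used because it is the convention such studies report and it
reproduces published pairs like 1.2 ± 0.42 from integer score vectors
(eight 1s, two 2s), which the population SD does not. The exhaustive
multiset search (`reconstruct_score_multisets`, 1001 candidates at n = 10)
matches each value at the precision it is printed with: a pair printed as
2.2 ± 1.1 is matched at one decimal — no integer multiset reproduces
"1.10" at two decimals — while 1.2 ± 0.42 is matched at two.
Reconstructed surveys are derived artifacts for testing and demonstration,
not recovered raw data.

## Problem sizes and runtime

The suites validate on deliberately modest sizes — single frames for
rendering checks; 8–40 frame videos for unit tests; 4 × 30 frames (640×480)
for jitter-sweep tracking accuracy; a 10-subject × 100-frame cohort for
stability recovery; 20 fluorescence pairs for area recovery; ≤ 400-pixel
crops for the brute-force Lloyd equivalence oracle. These sizes give the
Monte-Carlo estimates a few percent of sampling error, an order of
magnitude inside the asserted margins. The full test suite runs in about
90 s and the acceptance script in about 70 s on one CPU; a full 10-minute,
9000-frame recording tracks in about 6 minutes at ~40 ms/frame.

## Known limitations

- Clinical recordings and photographs behind the published stability and
  area numbers are not public, and the original pixel→mm calibration is
  unstated; millimetre-scale comparisons against the published per-position
  ranges/SDs are therefore qualitative. The package demonstrates *recovery
  of known ground truth* on synthetic data instead.
- The white-jitter motion model and Lambertian-free flat-color scene do not
  capture specular highlights, saliva films, illumination drift, or motion
  blur; passing recovery tests bounds algorithmic error, not robustness to
  those effects.
- Per-frame independent k-means assumes the three color classes stay
  separable; heavy color cast or a marker visually merging with shadowed
  tissue defeats it (such frames surface as invalid rather than as silent
  misses, provided `max_color_distance` is tight for the scene).
- The bleached-area estimate depends on `drop_fraction`; the default 0.3 is
  a design choice, and the monotone dependence (higher threshold, smaller
  mask) is exposed so users can report sensitivity.
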