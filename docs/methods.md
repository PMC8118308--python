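# Methods

This note documents the models and procedures implemented in
`crystalscope`, the tunable parameters and their defaults, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the design was genuinely open.

## SHG needle morphometry

**Model.** An SHG frame is modeled as bright, approximately straight,
approximately constant-width needle objects (crystalline cholesterol) on a
dark background. The pipeline recovers the set of independent needles and
reports count, density per mm², and per-needle length.

**Binarization.** Otsu's method on a 256-bin histogram spanning
[min, max] of the frame; the threshold is the bin center maximizing the
between-class variance and the mask is `intensity > threshold`
(`skimage.filters.threshold_otsu` behind a wrapper that pins the binning
and rejects constant frames). Splits that pass through an empty histogram
gap tie exactly in between-class variance; the implementation returns one
attaining bin and the test suite checks attainment rather than an
arbitrary argmax index. A Gaussian pre-smoothing of σ = 1 px
(`smooth_sigma_px`, 0 disables) is applied before thresholding: it leaves
the half-maximum contour of a needle in place while suppressing
noise-induced breaks in dim edges, which otherwise fragment needles at
low signal-to-noise ratio and bias lengths low. A constant
(background-only) frame yields an empty result rather than an error.

**Watershed splitting.** Touching objects are split by marker-based
watershed on the negated Euclidean distance transform (EDT), with markers
the h-maxima of the EDT, default h = 1 px. One subtlety: the rasterized
EDT ridge of a rotated needle carries sub-pixel dips (values alternate
between, e.g., 2.0 and √2), and the discrete h-maxima *set* therefore
fragments along a single needle even though every fragment's topographic
prominence is below h. The prominence rule is enforced exactly by a
post-pass that merges adjacent watershed basins whose separating EDT
saddle rises to within h of the lower of the two basin peaks (union-find
over basin adjacency, processed in descending saddle order). The result:
one label per straight needle at any orientation, a clean split at genuine
necks (the dumbbell case), and conservation of the foreground partition.

**Crossing decomposition.** Watershed on the EDT cannot separate crossing
needles: the junction is the widest point, so its ridge either swallows
both needles' ridges into one marker (steep crossings) or the junction's
double-peaked "bowtie" profile cuts the cross *transversally* into two
chevrons (shallow crossings). Neither yields per-needle objects. The
pipeline therefore adds a decomposition stage on each connected component:

1. *Single-needle test.* Fit the component's axis by total least squares;
   if the 90th-percentile perpendicular residual is ≤ 2.4 px
   (`axis_residual_p90_max`; a needle's half-width plus anti-aliasing) or
   the component fills ≥ 0.72 of its minimum-area oriented bounding
   rectangle (`rect_fill_single_min`), it is a single needle and is left
   intact. Calibration on rendered fields separates the two populations
   widely (needle residuals ≤ 1.6 px across orientations, widths 1.5–5 px
   and SNR ≥ 10; crossing components ≥ 3.2 px).
2. *Line extraction.* Hough-transform peaks (0.5° angular resolution,
   mutually distinct by ≥ 4° or ≥ 10 px in offset) are re-ranked by how
   many pixels their inlier band (half-width `needle_halfband_px` = 2 px)
   explains, then accepted greedily only when a candidate explains enough
   pixels no accepted line already claims (≥ max(8, 15%) of the
   component) — this drops tilted near-duplicate chords of an
   already-claimed needle. Pixels are assigned to the nearest accepted
   line and the assignment is refined by two rounds of per-part total
   least squares ("k-lines"), which removes the Hough quantization from
   the recovered needle geometry.

Components that fail to produce at least two needle parts keep their
watershed labels, so the stage is conservative; it can be disabled with
`split_crossings=False`.

**Overlap rejection.** Each object's minimum-area oriented bounding
rectangle (rotating calipers over the convex hull of its pixel-square
corners) is intersected with every other object's rectangle; an object
fails when the covered fraction of its own rectangle exceeds
`overlap_fraction_max` (default 0.2). Geometry note: for two needles of
length L and width w crossing at angle θ, the shared rectangle area is
≈ w²/sin θ, so the covered fraction is ≈ w/(L sin θ). High-aspect needles
crossing steeply therefore legitimately fall *below* the 0.2 default
(w/L ≈ 0.075 for 40 × 3 px needles at 90°): overlap rejection at this
threshold is the operative filter in the shallow-crossing regime, and the
synthetic generator's forced crossings default to that regime (below).
Objects smaller than `min_object_px` (default 8 at 512×512 — a
noise-speck floor, configurable and logged) fail on size instead and do
not count toward anyone's overlap.

**Length and orientation.** Length is the maximum Feret (caliper)
diameter over the object's pixel-square boundary (centers ± 0.5 px), via
the convex hull, times the pixel size: exact for straight needles, robust
to watershed nibbling, and giving a single pixel a length of one pixel.
Orientation is the angle of the maximizing chord folded to [0°, 180°);
for very thin objects the chord is ambiguous by ± atan(w/L). A skeleton
geodesic length (longest shortest-path along the morphological skeleton)
is available with `length_metric="skeleton"` for curved objects. Physical
pixel size is a required input everywhere; lengths are px × μm/px.

**Density.** Passed-object count over the analysis area — the full frame
by default, or a supplied plaque mask's area. Both conventions are
supported because "per unit area" and "per plaque area" differ only in the
denominator; the result records which was used.

## Synthetic SHG fields

`generate_needle_field` renders needles as anti-aliased rotated rectangles
(separable area-weighting, exact for axis-aligned edges and within a
fraction of a pixel otherwise) at amplitude 100 over background 10, with
additive Gaussian noise (`noise_sd`; 10 for an SNR-10 study, 0 for
noiseless oracles). Defaults are a 512×512 frame at 0.5 μm/px with 40
needles of fixed 20 μm length and 3 px width; lengths can instead be drawn
from gamma or log-normal families. The ground-truth pixel set of a needle
is exactly the set recovered by thresholding the noiseless render at
background + amplitude/2, which the test suite verifies.

Placement enforces a 3-px clearance between independent needles
(rejection sampling with bounded retries; an over-crowded request
raises). Forced crossing pairs intersect near both midpoints (offset
± 10% of length) at a relative angle drawn uniformly from 18°–22°. The
angle range is a deliberate design choice: in that regime the crossing
needles' bounding rectangles share well above 20% of their area
(w/(L sin θ) ≈ 0.26–0.35 for the default geometry), so rectangle-overlap
rejection at the 0.2 default is the operative filter; at steep angles the
shared area is a small fraction of each needle and such crossings are
intentionally not rejected at that threshold.

The additive-Gaussian noise model (no Poisson component) reflects
frame-averaged detection, where shot noise is near-Gaussian. The
generator does not simulate a point-spread function, SHG phase matching,
or polarization dependence; passing tests demonstrate the correctness of
the measurement pipeline on geometrically faithful scenes, not robustness
to optical blur or coherent imaging artifacts.

## Hyperspectral composition analysis

**Reference model.** Each species is a sum of Gaussian bands
(center, FWHM, relative amplitude), peak-normalized on the evaluation
axis. Anchored centers: the CH₂ stretch at 2845–2850 cm⁻¹ that carries
lipid SRS contrast; the =C–H stretch at 3010 cm⁻¹ (cholesteryl linoleate,
two C=C per acyl chain) and 3005 cm⁻¹ (oleate, one C=C) with linoleate's
amplitude (0.35) above oleate's (0.15); the protein CH₃ envelope at
2930/2960 cm⁻¹; the ester carbonyl at 1740 cm⁻¹ present in both
cholesteryl esters and absent in cholesterol monohydrate; the sterol C=C
near 1674 cm⁻¹ and protein amide I near 1655 cm⁻¹ giving the fingerprint
axis non-ester structure. Widths and relative amplitudes are package
defaults chosen to reproduce those qualitative orderings; the band table
is data, editable per run. The CH-stretch acquisition axis is
2825–3075 cm⁻¹ at 5 cm⁻¹ (51 channels); fingerprint point spectra use
1600–1800 cm⁻¹ at 2 cm⁻¹. The two windows are always analyzed as separate
axes, never concatenated, because they come from different instruments.

**Cube synthesis.** Pixels are exact linear mixtures of the
peak-normalized references (by class label or explicit weight maps;
"amorphous lipid" maps to 0.8 oleate + 0.2 linoleate as a droplet-like
CH₂-rich composition) plus i.i.d. Gaussian noise. Linearity at zero noise
is exact and tested.

**ROI spectra and smoothing.** An ROI spectrum is the per-channel mean
over the ROI pixel set (disk, ellipse, polygon or mask; disks contain the
pixels whose centers lie within the radius). Trace smoothing is a
not-a-knot cubic spline resampled to 1 cm⁻¹ — exact at the original
samples and exact for polynomials up to degree 3.

**Decomposition.** Spectra are baseline-subtracted (spectrum minimum —
the simplest defensible choice given offset-plotted source traces) and
peak-normalized, then fit as a non-negative (conic) combination of the
library by NNLS. Fractions are coefficients normalized to sum 1;
`residual_rms` is the RMS misfit on the normalized scale. The whole chain
is invariant to positive scaling of the input. NNLS is the minimal
quantitative formalization of "comparison against reference standards":
it reduces to exact assignment for pure spectra and degrades gracefully
for mixtures. Note the min-subtraction makes an exact conic combination
representable only up to the baseline shift, so noiseless residuals are
~1e-9 rather than 0; recovered fractions are still exact to 1e-6.

**Band detection.** The trace is lightly denoised (Savitzky-Golay,
quadratic, 7 samples), spline-resampled to 1 cm⁻¹, and searched for local
maxima (endpoints are never peaks). A band is present when a peak inside
the window (3010 ± 20 cm⁻¹ or 1740 ± 20 cm⁻¹) has topographic prominence
≥ 0.12 of the trace's dynamic range. The prominence floor is a
calibration: across 500 noise realizations at SNR 20 the largest spurious
in-window prominence for band-free species was 0.10 and the smallest
genuine linoleate 3010 prominence was 0.23, so 0.12 separates the
populations with margin on both sides (oleate's weaker 3005 shoulder
straddles the floor and its flag is treated as informative, not
diagnostic). Both the windows and the floor are exposed in configuration.

**Classification rules**, in order: CE_DOMINANT when pooled
oleate+linoleate fraction > `ce_fraction_min` (default 0.5 — the explicit
operationalization of "CE-dominated"); FREE_CHOLESTEROL when the
monohydrate fraction > 0.5; PROTEIN when the protein fraction > 0.5; else
AMORPHOUS_LIPID when `residual_rms` < 0.1, else INDETERMINATE. Pooling
the two esters first makes the call robust to their strong spectral
collinearity (they differ only in the 3005/3010 shoulder). Because the
default amorphous-lipid composition is itself an ester mixture, such
pixels classify as CE_DOMINANT by rule order — spectral unmixing alone
cannot distinguish amorphous from crystalline esters; that distinction is
SHG's job. The unsaturation flag is attached on CH-stretch axes and the
ester flag on fingerprint axes; an axis covering neither diagnostic
window is rejected.

## Crystal burden

Burden = 100 × (crystal area)/(plaque area), areas in μm². The crystal
mask is plaque pixels above an Otsu threshold computed *within the
plaque* (the dark exterior would otherwise dominate the histogram); a
fixed threshold is also supported. Otsu always produces a split, so with
the Otsu strategy the bright class counts as crystal only when its mean
exceeds 1.5× the dim class's mean (`min_contrast`) — a crystal-free
plaque then reports 0 rather than half its noise. The measure is an area
ratio on 2-D sections; it is labeled as such even where a volume fraction
is the quantity of ultimate interest. The plaque mask is a required
input: plaque outlines are drawn by morphology in practice, and automatic
plaque segmentation is out of scope. The synthetic section generator
meets a requested crystal-area fraction exactly up to one pixel
(budgeted cluster growth inside the plaque ellipse).

## Statistics

**Mann-Whitney U.** Statistic U of the first sample from midrank sums
(U ∈ [0, n₁n₂]; U(a,b) + U(b,a) = n₁n₂). For n₁+n₂ ≤ 12 the two-sided p
is exact: the null distribution of U is enumerated over all C(n₁+n₂, n₁)
group labelings of the pooled midranks, p = min(1, 2·min(P(U≤u),
P(U≥u))). Above that, a normal approximation with tie-corrected variance
and 0.5 continuity correction toward the mean. Both branches agree with
independent implementations to machine precision on tie-free data. The
normal approximation deviates from the exact p by up to ~0.04 at the
smallest sizes (n = 3+3, mid-range U), which is why the exact branch
exists; the crossover at 12 keeps enumeration under a thousand labelings.

**t tests.** Student two-sided t via pooled variance (default), Welch, or
paired differences (`scipy.stats` underneath). The pooled unpaired
variant is the package default; the paired variant exists because paired
designs appear in this literature. On a fixed 4-vs-4 sample with
overlapping groups the pooled-t p agrees with a 10⁶-draw permutation
oracle to < 0.001; with completely separated groups a permutation p is
floored at 2/70 ≈ 0.029 while the t p can be far smaller, so permutation
validation is only meaningful away from complete separation.

**Group comparison.** Per-image metric values (density, mean/median
length, burden) are pooled per group; with animal identifiers supplied,
per-image values are first averaged within animal and the test runs on
animal means (both modes provided because pooling images treats fields,
not animals, as the experimental unit). Exactly two groups are compared.

**Study simulation.** The paper-analog design used for validation:
2 control vs 3 "infected" animals, alternating 3–4 images per animal
(7 vs 10–11 images), infected needle mean length 0.67× control and mean
density 1.5× control, Mann-Whitney on per-image mean length. Problem
sizes were chosen to keep a 400-study validation run within a few minutes
on one CPU while leaving the effect far above the detection floor:
256×256 px fields at 0.5 μm/px, control images Poisson(24) needles of
gamma-distributed length (shape 6, mean 15 μm, truncated to 4 μm–image/3)
at SNR 10. Under these conditions the length decrease is detected
(p < 0.05, correct direction) in ≈ 100% of simulated studies and
identical groups are flagged in ≈ 5%.

## Reproducibility

One top-level seed drives every stochastic stage through independently
spawned substreams (`numpy` SeedSequence); identical configs reproduce
byte-identical numeric outputs, and the pipeline writes a manifest with a
config echo, SHA-256 checksums of all artifacts, per-stage wall-clock and
captured warnings. Generators are pure functions of their parameters
including the seed.

## Known limitations

* The morphometry assumes straight, approximately constant-width needles;
  strongly curved or plate-like ("cuboidal") crystals are measured by the
  same Feret/skeleton metrics but the crossing decomposition and the
  overlap geometry are tuned for needle habits, and shape classification
  is out of scope.
* Steep high-aspect crossings are intentionally not rejected at the 0.2
  rectangle-overlap default (see geometry note above); lowering
  `overlap_fraction_max` trades that off against false rejection of
  near-touching needles.
* Otsu thresholding presumes a bimodal histogram. A frame of pure noise
  still produces a split; the speck-size floor and the burden contrast
  guard mitigate but do not eliminate spurious foreground in signal-free
  data.
* The spectral model is a Gaussian band approximation with anchored
  diagnostic centers; it supports exact-recovery validation of the
  unmixing and band logic but is not a substitute for measured reference
  standards, whose band shapes, Fermi resonances and baselines differ.
* Amorphous vs crystalline lipid cannot be distinguished spectrally here
  (both are ester-dominated); the distinction requires the SHG channel.
* Synthetic scenes omit optical blur, uneven illumination, tissue
  autofluorescence and spatially correlated noise; accuracy figures from
  the validation suite are upper bounds with respect to those effects.
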