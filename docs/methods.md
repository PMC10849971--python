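# Methods

This note records the models, parameter conventions and design choices
behind each stage of the pipeline, and what the synthetic-data tests do
and do not establish about real microscopy data.

## Coordinate and intensity conventions

The pixel grid is 0-based `(row, col)`; a pixel's physical center is
`(index + 0.5) × pixel_size` µm. Angles are degrees in [0, 360),
counter-clockwise, 0° at the +x (column) axis, measured about a
compartment's centroid. Intensities are arbitrary-unit floats; the TIFF
writer quantizes to 16-bit and records the scale factor in the channel
map so reads invert it. No bit depth or physical intensity unit is
assumed anywhere downstream.

## Synthetic scenes

The generator emulates the geometric and statistical structure the
quantification assumes, not the biology or the optics:

* WT compartments are rasterized discs (optionally ellipses or crescents)
  with per-channel baseline levels; an F-actin density channel is always
  emitted (level 1.0 inside every compartment unless overridden).
* Angularly localized marker domains are wrapped-Gaussian bumps in border
  angle, `amplitude × Σₖ exp(−½((Δθ + 360k)/width)²)`, added to the disc
  baseline. Any smooth unimodal bump would serve; the wrapped Gaussian
  was chosen because its peak is differentiable, which makes peak-recovery
  tests sharp. Doubling the amplitude doubles the signal-minus-baseline
  at the peak.
* EGFP coverage marks the first `round(fraction × n)` mask pixels in
  row-major order positive, so the realized coverage fraction is exact and
  boundary cases (exactly 50%) can be constructed.
* Noise is additive Gaussian clipped at zero — the weakest model that
  still exercises thresholding. One seed governs a scene; per-channel
  noise streams are spawned from it in sorted channel order, so adding a
  compartment never perturbs the noise field.
* Z-stacks give each channel a Gaussian per-slice mean profile in slice
  index (a point mass when `z_sd = 0`), emulating basal/middle/apical
  marker stratification. Cell fields draw per-marker Bernoulli positivity
  and Gaussian intensities (clipped at 0) around positive/negative means.
  Gene lists are built from a designed overlap structure
  (|A|, |B|, |C∩D∩E|) realized exactly, with remaining members unique per
  list.

Every generator returns a JSON-serializable manifest of the true
parameters (mask pixel sets, areas, peak angles, axis classes, slice
means, positivity counts, overlap sets), each recomputable from the
emitted artifact by independent means when noise is zero.

What the generator does **not** model: point-spread functions, uneven
illumination, autofluorescence, cell-scale texture, segmentation-relevant
debris, or any self-organization dynamics. Passing tests therefore show
that the measurement rules are implemented correctly and are robust to
additive noise at the tested levels — not that the pipeline segments
arbitrary real coverslips well. Threshold choice on real data remains the
user's responsibility.

## Compartment segmentation

Detection thresholds the chosen channel (Otsu's method by default, fixed
value by config) and labels 8-connected components. The size filter
implements the stated formula exactly:

    lower size limit = A_max / 10^((A_max − A_cell) / 2)

with both areas supplied by the user in the working unit — they are
defined manually from the images, so the package refuses to guess
defaults. Note the formula's exponent makes the limit astronomically
small for realistic µm² inputs (A_max − A_cell in the thousands); it is
implemented as printed, with areas interpreted in whatever unit the user
works in, and an absolute `min_area` floor available as the practical
alternative.

Features: area = pixel count × pixel_size²; perimeter is the length of
the marching-squares boundary trace after Douglas–Peucker simplification
with a 0.7 px tolerance — the raw trace's digitization stairs would
inflate a disc's perimeter ~5% and push circularity (4πA/P²) down to
0.91, while the simplified trace yields ≥ 0.96 for discs and ~0.79 for
large squares (the π/4 limit). Circularity may slightly exceed 1 on
small discs; this is digitization, not an error. Nearest-neighbour
distance is centroid-to-centroid (the simplest convention; nothing in the
measurement fixes edge-to-edge instead). Coverage calls are strict:
exactly half the mask EGFP⁺ is *not* covered.

## Radial profiling

One inward line per border pixel (4-connected mask boundary, ordered by
angle about the centroid), sampled every pixel with bilinear
interpolation down to the requested depth, which must be smaller than the
equivalent radius. A line any of whose sample points leaves the mask (or
the image) is skipped entirely and propagates as a missing value — never
a zero — through all downstream means. The sampling step and interpolant
are pinned (1 px, bilinear) so results are resolution-independent and
bit-reproducible.

Alignment rolls every channel of a compartment by the same offset so the
CER1 maximum (lowest index on ties) sits at index 0; compartments lacking
CER1 are resampled without shifting. Length equalization linearly
interpolates the circular profile onto the longest border length in the
cohort. Index→angle mapping after equalization is linear around the
circle; this is exact for circular borders and approximate for concave
shapes, which are excluded from polarity work anyway.

## Polarity classification

Normalized profiles are marker ÷ (F-actin + ε) with ε = 10⁻⁹ as a
division guard. The rolling average at each index takes the mean of all
values within `disc_radius/8` of arc in either direction (inclusive
boundaries, circular wrap; missing values excluded per window); with n
points on a circularized border the half-window is
`⌊n/8 / 2π⌋` points. A window covering the whole circle returns the
global mean — a constant profile, which is simply not polar.

A marker is polar iff max − min of its smoothed profile **exceeds** 0.1
normalized intensity (strictly; a range of exactly 0.1 is not polar).
The peak is the smoothed argmax, lowest index on ties. Axis classes use
closed windows: anti-polar for a TBXT peak 135°–225° from the CER1 peak
(boundaries included), syn-polar for ≤ 45°, otherwise unrelated. The
wording behind these windows ("between", "within") does not fix
open/closed; closed was chosen and is pinned in tests.

Multi-pole exclusion automates a step originally done by eye. A pole is
a circular local maximum whose **prominence** — height above the highest
saddle connecting it to a larger pole — exceeds the 0.1 threshold, with
poles closer than one full rolling window merged. Prominence, rather
than "exceeds global minimum + 0.1", is the operative criterion because
the global minimum of a noisy profile is itself a noise trough: with
noise at 10% of domain amplitude, the naive rule excludes roughly a fifth
of genuinely single-pole compartments, while the prominence form keeps
the same meaning (a second domain must rise > 0.1 above the profile
between the poles) and is stable. Two or more poles on either marker
exclude the compartment from axis classification; the exclusion can be
switched off.

"Highest averaged quadrant value" in the source description is
operationalized as the argmax of the rolling-average profile: the rolling
window already performs the local averaging, and no quadrant partition is
defined anywhere else in the procedure.

## Haematopoietic quantification

Cell objects are connected components of an above-threshold marker
channel with a minimum-size gate; each carries the mean of every channel
over its pixels (NaN pixels from WT-mask exclusion are excluded from
means and never seed objects). The focus rules are implemented exactly
as counting rules — strictly more than 20 cells to classify; uni-lineage
tolerates at most two cells lacking the marker and no CD43-only cell;
multilineage needs ≥ 3 positive cells for each of ≥ 2 assessed markers —
with multilineage taking precedence when both patterns hold (a focus with
three or more cells of each of two lineages expresses two marker types by
construction). The CD43-only veto is stated only for the uni-lineage
case and is applied only there. Spatial grouping (cells linked within a
configurable radius, components kept) is a reproducible stand-in for
manual focus partitioning; externally supplied groupings are accepted.

Haemoglobin chains are normalized by the coverslip-wide mean object
pan-haemoglobin intensity; the per-cell ratio is ε/γ, reported missing
(not dropped) when γ = 0. All outputs are invariant to global intensity
rescaling.

Z-profiles: the stack bottom is the lowest slice whose mean exceeds a
configurable noise floor (no focus metric is defined by the source
procedure, so the floor stands in for "in-focus"); per-slice means above
the bottom are expressed as percent of each channel's maximum. Replicate
profiles are aligned on their bottoms, their normalized percentages
averaged index-wise (shorter profiles contribute missing values), and the
average renormalized so the maximum is again 100%.

Fold changes are 2^−ΔΔCt with ΔCt = Ct(target) − Ct(endogenous control),
differenced against a calibrator sample.

## Marker-list statistics

The hypergeometric upper tail P(X ≥ k) comes from the survival function
of `scipy.stats.hypergeom` (log-space internally); k = 0 returns exactly
1. Tests verify it against exhaustive binomial-coefficient enumeration
to < 10⁻¹⁰ relative error for all universes up to N = 30.
Benjamini–Hochberg uses the standard step-up (via statsmodels), one
family per comparison matrix.

For the Jaccard-difference statistic, "unique overlap" is read as
exclusive overlap — A = (C∩D)\E, B = (C∩E)\D — since the adjective is
otherwise vacuous; `overlap="plain"` switches to plain intersections for
sensitivity analysis. This reading is the module's main interpretive
risk. The empirical null draws R size-matched triples uniformly without
replacement from the supplied genome (the genome/universe is a required
explicit input); the add-one estimator p = (1 + #{Δ_null ≥ Δ_obs})/(R+1)
keeps p ≥ 1/(R+1) so −log₁₀(P) is finite, and ties count toward the tail
(conservative). Null calibration is verified by KS uniformity of p over
500 replicates at R = 199.

## Problem sizes and tolerances

The shipped tests and the acceptance script use synthetic cohorts sized
for sharp statistics at desk scale: 200 single-compartment scenes
(120×120 px, radius 40 µm, domain amplitude 1.0 ≈ 10× the polarity
threshold, noise σ = 0.1) for axis recovery; 500 × R=199 draws from a
1000-gene genome for null calibration; n = 1000 cells for ratio
recovery; exhaustive sweeps elsewhere. Axis-recovery accuracy is ≥ 95%
under these conditions (observed: 100%), noiseless peak error is below
one border step, and the ratio median recovers the true value within 5%.

## Known limitations

* Angular index→angle mapping after equalization assumes near-uniform
  border-point spacing; strongly concave compartments violate this (they
  are excluded from polarity analysis, but their aligned profiles are
  still emitted).
* The Otsu default assumes a bimodal intensity histogram; dim or sparse
  scenes need a fixed threshold.
* The multi-pole rule counts poles of the smoothed profile; domains
  narrower than the rolling window are smoothed away and will not be
  flagged.
* The empirical-null sampler treats genes as exchangeable; no expression-
  level or gene-length matching is attempted.
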