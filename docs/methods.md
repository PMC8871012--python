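# Methods

## Measurement model

A spine is a sequence of up to 17 vertebra boxes ordered superior to
inferior, each a quadrilateral of four corner landmarks with a detection
score in [0, 1]. Coordinates are image pixels with the raster convention:
origin top-left, x rightward, y downward, 0-based indices. Endplate tilt is
the inclination of an endplate measured from the left corner to the right
corner, positive when the right corner is lower on screen (clockwise); with
y growing downward this makes mirror symmetry exactly assertable: reflecting
the landmarks left↔right negates every tilt, flips the reported convexity
side, and leaves the angle and apex unchanged.

The Cobb angle is |tilt of the superior end vertebra's top endplate − tilt
of the inferior end vertebra's bottom endplate|. The float value is kept
internally; the integer report rounds half away from zero, matching how
clinical readings are recorded.

### Stage order and the individual rules

`measure_cobb` runs: score filter → outlier rejection → imputation → apex →
end vertebrae.

**Score filter.** Boxes with score ≤ 0.5 (strict `>` keeps the threshold
semantics of "more than") are dropped. Fewer than 5 surviving boxes makes a
measurement infeasible — with fewer centers neither the chord nor the tilt
extrema are meaningful.

**Outlier rejection.** Adjacent vertebrae cannot be laterally far apart, so
a box whose x-center deviates from the mean x-center of its two vertical
neighbours by more than half its own width is rejected. The first and last
boxes, having one neighbour, are compared to that neighbour alone.
Violations are resolved greedily: flag the worst offender, then re-check the
remaining boxes against their nearest still-good neighbours. The one-shot
variant of the rule would also flag the two innocent neighbours of a grossly
displaced box, because the displaced center contaminates their neighbour
mean; greedy refinement isolates the true offender while keeping the
half-width threshold and the boundary rule unchanged.

**Imputation.** At most two rejected boxes are rebuilt (more than two means
detection failed badly enough that a measurement should not be reported).
The new center x comes from a least-squares cubic of center-x as a function
of center-y over the 6 good boxes nearest in y; the local window matters: a
single global cubic over all 15–16 good centers drifts more than 2 px from
a sinusoidal centerline at clinically common amplitudes, while the windowed
cubic stays within a pixel. With fewer than 4 good boxes in reach the fit
degrades to linear. Width, height and endplate tilt are linearly
interpolated between the nearest good boxes above and below (copied from
the single neighbour at the sequence ends), and rebuilt boxes are flagged
`imputed`.

**Apex.** The apex is operationalized as the most laterally displaced
vertebra: the center with maximum perpendicular distance from the chord
joining the first and last centers. If every center lies within 1 px of the
chord the spine is reported straight (angle 0, apex at the middle index).
The convex side is the side with the larger summed gap profile — the
corner-to-corner distances between adjacent boxes (bottom-left→top-left on
the left side, bottom-right→top-right on the right); on a curved spine the
fan of endplates opens on the convex side, so that side accumulates the
larger total.

**End vertebrae.** Superior end = argmax of |top-endplate tilt| over
indices ≤ apex; inferior end = argmax of |bottom-endplate tilt| over
indices ≥ apex. The apex is eligible on both sides, so the candidate set is
never empty even when the apex sits at a sequence end; ties break toward
the vertebra farther from the apex, which is the clinically conservative
choice (longer measured segment).

Sequences shorter than 17 (minimum 5) are accepted throughout; nothing
assumes a complete detection.

## Torso cropping

The pre-processing detector is classical by design: 8-neighbour,
radius-1 local binary patterns (ties z = 0 count as 1, bits packed
clockwise from the top-left neighbour — any fixed order works, this one is
pinned by tests), 256-bin L1-normalized code histograms per window (border
pixels whose 3×3 neighbourhood leaves the image are skipped, never padded),
discrete AdaBoost over decision stumps on histogram bins (β = ε/(1−ε), ε
clamped to [1e−10, 0.5−1e−10]), a default 3-stage rejection cascade, and a
row-major, coarse-to-fine sliding-window scan. The crop is the union
bounding box of the positive windows. Window size, stride and stage count
are configuration, not claims — they should be re-tuned for any real
deployment.

## Detection support math

The focal loss is the penalty-reduced variant used for keypoint heatmaps:
positives (τ = 1) contribute (1−ρ)² log ρ, every other cell contributes
(1−τ)⁴ ρ² log(1−ρ), averaged over the map and negated. Predictions are
clamped to [1e−7, 1−1e−7] to keep the logs finite. Landmark error is the
mean Euclidean distance over index-aligned point pairs.

Offset-map encoding places each vertebra center in the grid cell
floor(center/stride) with τ = 1 and a Gaussian skirt (σ = 2 cells, needed
for the (1−τ)⁴ down-weighting to have soft values to act on), stores the
sub-cell remainder in two center-offset channels and the center→corner
displacements in eight corner channels. Decoding takes the top-k 3×3
non-maximum-suppressed positive peaks and inverts the construction, so the
round trip is exact up to the stored offsets; the stride is a free
parameter (default 4).

## Synthetic phantoms

The generator emulates the data regime the measurement stage sees after
detection: a single-arch scoliotic spine on a 512×1024 canvas. The
centerline is x(y) = A·sin(π(y−y₀)/L) inside the arch (default y₀ = 100,
L = 820) and vertical outside; 17 vertebra centers are equally spaced in y
through the arch, each box's endplates are perpendicular to the local
tangent, sizes taper linearly from 90×30 px (thoracic) to 120×45 px
(lumbar), scores are uniform in [0.6, 1.0], and corner noise is i.i.d.
Gaussian with σ = 1 px by default — a minimal stand-in for detection
jitter. The true Cobb angle is analytic: the spread of tangent angles
atan(dx/dy) over the vertebral centers, which for a half-sine arch is
2·atan(Aπ/L·cos(π/(2n))). `amplitude_for_cobb` inverts this by bisection to
0.1°.

What the phantom does not emulate: radiographic texture, ribs and pelvis
shadows, multiple or minor curves, vertebra-specific shape variation,
correlated (non-i.i.d.) detector errors, and missing-in-the-middle
detections with wrong ordering. Passing phantom tests therefore
demonstrates the geometric correctness and noise robustness of the
measurement chain, not performance on clinical images; the packaged
70-image measurement set covers the latter at the statistics level.

Vertebra widths default to 90–120 px deliberately: on normalized AP
radiographs vertebral bodies are wide relative to the inter-vertebral
lateral shift, and the half-width outlier threshold implicitly assumes
that. Much narrower boxes would make the boundary outlier rule fire on
legitimate steep curves near 80°, a property of the rule rather than of any
particular image.

## Agreement statistics

The packaged fixture (`cobb_measurements.csv`, SHA-256 pinned) holds 70
images × three readings — specialist reference observer `obs1`, second
observer `obs2`, automated `auto` — with severity strata <10°, 10–25°,
>25–40°, >40° (6/19/15/30 images). Only raw angles are stored; percentage
accuracy (100 − 100·|ref−test|/ref, unclipped and undefined at ref = 0),
signed differences, ±5° shares, medians and IQRs are always recomputed.
Quartiles use linear interpolation between order statistics; other quartile
conventions move IQR endpoints by ~0.1–0.3 but never the medians of this
set.

ICC is the two-way random-effects, absolute-agreement form. `icc` defaults
to single measures, ICC(2,1) — the agreement of one rating, which is the
form that answers "can the automated reading replace one observer's
reading". The average-measures form ICC(2,k) is exposed via
`form="average"`; on this fixture it yields 0.995/0.957/0.954 for
obs1–auto/obs1–obs2/obs2–auto versus 0.991/0.917/0.912 for single measures.
Pearson r comes from scipy; group comparisons use the two-sided
tie-corrected normal-approximation Mann–Whitney U for ordinal variables and
the 2×2 chi-square without continuity correction for nominal ones.

## Numerical choices and problem sizes

* Zero-curve tolerance: 1 px perpendicular distance from the chord.
* Tilt computed with atan2, range (−90°, 90°) for valid boxes; coincident
  edge corners raise rather than guess.
* Rounding half away from zero for the integer report.
* Bisection for amplitude inversion to 0.1°.
* Property tests run 100–200 phantoms per claim with fixed seeds; the
  noisy parameter-recovery check uses 200 phantoms with true angles uniform
  on 5–79° and σ = 1 px corner noise, giving a mean absolute error of
  about 0.8° (asserted ≤ 3°).

## Known limitations

Single major curve only — an S-shaped spine yields one angle for the
dominant arch and silently ignores the secondary curve. The apex definition
(maximum chord distance) and the curve-fit order are one reasonable reading
of "deepest part of the curve" and "curve fitting"; other operationalizations
exist. The torso detector is texture-based and will not separate a torso
from a textured background without retraining. The evaluation fixture is a
single-center 70-image set with integer-degree readings; its statistics
carry that granularity.
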