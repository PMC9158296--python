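# Methods

## The measurement

A femoral offset measurement on one radiograph uses four landmark groups
clicked by a rater: 5 points on each of the medial and lateral cortical
borders of the proximal shaft, 6 points around the projected femoral head,
and ≥3 points on the rim of a radio-opaque sphere of known diameter placed in
the plane of the femur.

**Cortical lines.** Each border is fitted with a *total* least-squares line
(first principal axis through the centroid, minimising orthogonal
residuals). The borders are near-vertical in a well-positioned radiograph,
where ordinary y-on-x regression is ill-conditioned; TLS is also invariant
under rigid motions of the image, which the whole measurement inherits.

**Shaft axis.** The axis is the bisector of the two cortical lines:
directions are sign-harmonised (flip one if the dot product is negative),
summed and normalised — the acute-angle bisector — and anchored at the
lines' intersection. Cortical borders are nearly parallel, so the
intersection lies far from the bone; that is numerically harmless because
only the point–line distance enters the offset. Exactly parallel lines
(|sin| < 1e−6 between directions) fall back to the mid-line through the
midpoint of the two canonical anchors, which is exact for the symmetric
cylinder silhouette.

**Circles.** Head and sphere are fitted with a Kåsa algebraic fit (linear
least squares on the implicit circle equation) refined by Gauss–Newton on
the geometric objective Σ(‖p−c‖−r)². The refinement matters for few-point
partial arcs, where the algebraic fit is biased toward small radii; the
reported RMS residual always comes from the geometric residuals of the
returned circle. Convergence tolerance 1e−13 relative step, cap 100
iterations; collinear point sets (smallest singular value < 1e−9 of the
largest) are rejected as degenerate.

**Calibration and offset.** `mm_per_px = sphere_diameter / (2·radius_px)`
with the sphere diameter 1 inch = 25.4 mm exactly. The offset is the
unsigned perpendicular distance from the head-circle centre to the shaft
axis, scaled to millimetres. Offsets are distances; no sign convention is
attached to them (signs live on rotation angles: external negative, internal
positive).

## The projection model

The simulator idealises the bench geometry: shaft axis vertical in the image,
X-ray beam perpendicular to it, orthographic (parallel-beam) projection. The
in-plane sphere calibration is exactly the parallel-projection idealisation,
so cone-beam magnification and fluoroscopic distortion are deliberately not
modelled. Consequences used by the tests:

- the head centre projects at horizontal distance `R·|cos(θ−θ0)|` from the
  axis — the cosine law the whole method rests on;
- the shaft cylinder's silhouette half-width is constant in θ, so the
  cortical lines do not move with rotation;
- the projected head circle keeps the head radius (a sphere).

`θ0`, the angular discrepancy between the radiographically aligned neutral
(actuator zero, trochanteric lines superimposed) and the rotation revealing
the full offset, is modelled as a single per-specimen parameter rather than
derived from trochanteric micro-anatomy: the bench work located the line
sources anatomically but did not quantify their 3-D geometry. Two
trochanteric surface points are nevertheless carried in the model, placed in
cylindrical coordinates about the shaft axis with the posterior radius
re-derived so both project to the same horizontal coordinate at actuator
zero; they reproduce the qualitative alignment behaviour (superimposed at 0°,
clearly separated at ±30°) and their exact placement is a documented free
parameter (defaults: anterior at 21 mm radius, azimuth +40°; posterior
azimuth −25°).

## Study-design defaults

`CohortConfig` encodes the emulated bench design; these defaults are the
package's definition of the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_specimens` | 11 | cohort size |
| `offset_mean_mm`, `offset_sd_mm` | 38.2, 4.9 | true-offset distribution (truncated > 0 by resampling) |
| `theta0_mean_deg`, `theta0_sd_deg` | −3.6, 5.6 | aligned-vs-true angular discrepancy |
| `angle_grid_deg` | ±30 and −10…+10 by 2 | 13 imaging angles (the enumerated bench grid) |
| `landmark_noise_sd_px` | 0.5 | isotropic Gaussian annotation noise, all roles |
| `mm_per_px_true` | 0.25 | detector scale (sphere radius 50.8 px) |
| `n_rater_rounds` | 3 | independent re-annotations per radiograph |

Randomness is split with counter-based `SeedSequence` keys
`(specimen, angle_index, round)`, so specimen *i* is bit-reproducible
independent of cohort size and each round re-noises landmarks independently
(modelling re-measurement of the same stored image).

The 0.5 px noise default is a round, plausible figure for careful manual
annotation at this detector scale (0.125 mm). It was chosen once as the
generator's definition of annotation quality; it produces a within-specimen
±10° curve range of ≈1.6 mm and an intrarater ICC ≈ 0.999, versus ≈2.7 mm
and 0.991 on the bench — i.e. the synthetic rater is somewhat better than a
human one, because real annotation error has structured components (border
ambiguity, arc foreshortening) beyond isotropic pixel jitter. Passing tests
therefore demonstrate correctness of the computation and recoverability
under idealised noise, not the full error budget of a human rater on real
fluoroscopy.

## Sweep definitions and conventions

- *True offset* = maximum of the per-specimen curve over the imaged grid
  (no interpolation between grid angles — the discrete max is the
  operational definition).
- *Aligned offset* = curve value at 0°; analysis errors out if 0° is absent.
- *Underestimation %* uses the true (maximum) offset as denominator.
- Ties for the maximum break toward the smallest |angle|, then toward
  internal (positive) rotation, and are flagged (`max_tied`).
- Rounds default to `mean_of_rounds` (averaged angle-by-angle before
  maximisation); `per_round` returns one sweep per round.
- `range_pm10` uses the closed interval [−10°, +10°].
- Cohort sd uses the n−1 denominator and is reported as null for n = 1.

## Reliability

ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)) from the
two-way ANOVA mean squares; verified in tests against a from-definition
sums-of-squares oracle and pingouin's ICC(A,1). Conventions: an all-equal
table (and any table whose rounds are bitwise identical per subject) is
defined as ICC = 1 — the mean-square route would return 1 − O(ε) because a
floating-point mean of identical values need not equal them; negative
estimates are reported unclamped; the interpretation bands are poor < 0.40,
fair-to-good for 0.40–0.75 inclusive (both published cut-offs are strict
inequalities, leaving the boundaries ambiguous; both map to the middle
band), excellent > 0.75. The bootstrap resamples subject rows with
replacement (a subject's rounds stay paired), 2000 replicates by default,
percentile 2.5/97.5 CI, explicit seed required.

## Problem sizes and numerical checks

The validation suite runs, among others: the cosine law end-to-end over
R ∈ {30…46} mm × θ0 ∈ {−10°…+10°} × 13 angles at 1e−6 mm tolerance (observed
error ~1e−14 mm); line/circle fits against brute-force oracles (fine angle
grid; Nelder–Mead) on 100 random noisy instances each; and parameter
recovery over 500 simulated cohorts at the default design. The acceptance
script uses 200 cohorts for its recovery summaries — enough that Monte-Carlo
error is far below the quantities' own spread — and 2000 bootstrap
replicates for the ICC CI.

One recovery subtlety is intrinsic to the design, not an implementation
artifact: the grid truncates and discretises θ0 ~ N(−3.6°, 5.6°), so the
population mean of the *nearest-grid-angle* statistic is ≈ −3.30° by
quadrature (the |θ0| > 11° tail maps to ±10°/±30°), and annotation noise on
near-tied neighbouring grid points pulls the simulated mean further to
≈ −3.1°. Recovery of the −3.6° discrepancy is therefore judged against the
sampling error of an 11-specimen cohort (5.6/√11 ≈ 1.7°), which the
simulated grand mean meets comfortably.

## Known limitations

- No image processing: the package consumes landmark coordinates, never
  pixels; automatic landmark detection is out of scope.
- Orthographic projection only; no cone-beam magnification, pincushion
  distortion, or out-of-plane sphere placement.
- Annotation noise is isotropic, homoscedastic and role-independent; real
  rater error is not.
- The trochanteric-line model reproduces alignment behaviour qualitatively;
  it is not an anatomically calibrated model of the greater trochanter.
- Offsets are unsigned; curves are analysed on the discrete imaged grid.
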