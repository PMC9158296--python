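# femoffset

Radiographic measurement of **femoral offset** — the perpendicular distance
from the femoral head's centre of rotation to the long axis of the proximal
femoral shaft — together with the rotation-sweep analysis and reliability
statistics used to validate the trochanteric-line alignment method for
finding the rotation at which a plain radiograph shows the *true* offset.

Femoral offset drives abductor tensioning, stability and leg-length
perception after total hip arthroplasty, and is templated preoperatively from
plain films. But a radiograph only shows the offset component parallel to the
image plane: at femoral rotation θ about the shaft axis the projected offset
is

```
d(θ) = R · |cos(θ − θ0)|
```

where `R` is the true (3-D) offset and `θ0` the rotation at which the
head-offset plane is parallel to the film (external rotation negative). Any
misrotation *underestimates* `R`. Two radiographic lines produced by the
anterior and posterior aspects of the greater trochanter superimpose at a
reproducible rotation close to `θ0`, giving a practical alignment cue. This
package implements the computational side of that method and everything
needed to validate it without bench data:

- **landmarks_io** — a landmark annotation schema (specimen, image, nominal
  rotation, role, pixel coordinates) with lossless CSV/JSON round-tripping;
- **geometry** — the measurement itself: total-least-squares lines through 5
  medial and 5 lateral cortical border points, their bisector as the shaft
  axis, a Kåsa-plus-Gauss–Newton circle through 6 femoral-head points, scale
  from a 1-inch (25.4 mm) calibration sphere in the plane of the femur, and
  the perpendicular head-centre-to-axis distance in millimetres;
- **simulator** — an orthographic projection of a parametric 3-D proximal
  femur at arbitrary rotation, emitting annotated landmark sets with
  controlled Gaussian pixel noise and exact ground truth;
- **sweep** — per-specimen offset-vs-rotation curves: true offset (curve
  maximum), aligned offset (value at 0°), underestimation (mm and %),
  rotation at maximum, and cohort descriptive statistics;
- **reliability** — intrarater repeatability via ICC(2,1) (two-way random
  effects, single measures, absolute agreement) with a subject-resampling
  percentile bootstrap CI;
- **cli / pipeline** — a thin `femoffset` command chaining
  `simulate → measure → sweep → icc` reproducibly from one seed.

## Worked example

`examples/02_rotation_sweep_cohort.py` simulates an 11-specimen cohort
(offsets ~ N(38.2, 4.9) mm, alignment discrepancy θ0 ~ N(−3.6°, 5.6°),
13-angle grid, three annotation rounds at 0.5 px noise), measures every
radiograph and summarises the sweeps:

```
11 specimens, 429 annotated radiographs

true_offset_mm        mean   37.02 mm  sd 6.35  median 35.09  range 27.41 to 50.44
aligned_offset_mm     mean   36.81 mm  sd 6.30  median 34.92  range 27.36 to 50.40
underestimation_mm    mean    0.20 mm  sd 0.25  median 0.05  range 0.00 to 0.78
underestimation_pct   mean    0.54 %   sd 0.61  median 0.19  range 0.00 to 1.73
rotation_at_max_deg   mean   -2.36 deg sd 4.08  median -2.00  range -8.00 to 4.00
range_pm10_mm         mean    1.25 mm  sd 0.51  median 1.10  range 0.65 to 2.43

specimens per rotation-at-maximum angle: {-8.0: 3, -2.0: 4, 0.0: 2, 2.0: 1, 4.0: 1}
```

Reading: the aligned (0°) measurement loses on average 0.2 mm (0.5%) against
the curve maximum for this cohort draw, and the rotation of maximal offset
scatters around a few degrees of external rotation — the projection-law
behaviour the alignment method exploits. `examples/03_intrarater_reliability.py`
prints `ICC(2,1) = 0.999, bootstrap 95% CI [0.998, 0.999]` for the three
rounds of the same cohort, and `examples/01_measure_single_radiograph.py`
shows a single measurement recovering `40·cos 6° = 39.781 mm` to machine
precision. The same stages are available from the shell:

```sh
femoffset pipeline --seed 1 --out-dir out/
```

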