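# cromkit

Automatic measurement of the cervical range of motion (CRoM) from
per-vertebra segmentations of paired flexion/extension lateral cervical
radiographs.

Evaluating cervical intervertebral instability — a key dynamic parameter in
the workup of cervical myelopathy — requires drawing reference lines on the
endplates of adjacent vertebrae in full flexion and full extension and
comparing the angles between the two poses. Done by hand this is slow and
observer dependent. `cromkit` automates the geometric half of that task: it
consumes labeled vertebra regions (from any instance segmenter, e.g. a
Mask R-CNN trained on the classes `c1`, `c2`, `c3toc7`) and turns them into
per-junction intersegmental angles and their flexion–extension difference.
Raw radiographs and segmentation-model inference are out of scope; the
package starts where the segmenter stops.

Intended users: medical-image-analysis researchers and engineers building or
validating spine-measurement pipelines.

## Method

For each pose and each junction Cn/Cn+1:

1. Regions are ordered by bounding-box `y` (cranial first), `c1`/`c2` pin
   C1/C2, and the remaining instances receive consecutive labels. Adjacent
   boxes form a continuous chain iff the vertical gap `d` between them
   satisfies `d < 0.5 · h(n)` (half the height of the cranial box); a
   violated junction is excluded and labeling skips the estimated number of
   missing bodies.
2. Each region's outer contour is reduced to its convex hull and then to a
   simple polygon with 3–4 vertices (Douglas–Peucker with a binary-searched
   tolerance; C1 uses the triangle form).
3. The facing edge pair between adjacent polygons is the pair minimizing
   the distance between edge midpoints. C1/2 is special: C1 contributes the
   longest side of its triangle (posterior arch), C2 the side to the right
   of its lower edge (posterior vertebral body).
4. The contour points near each selected edge — axis-aligned boxes keyed on
   the edge endpoints `(x1, y1)`, `(x2, y2)` and midpoint `(x_M, y_M)`, with
   a small margin and a proximity cut — form the band through which a total
   least-squares line is fitted (with trimmed refits).
5. The intersegmental angle follows from the tangent addition theorem,
   `tan θ = (a − b) / (1 + ab)` for slopes `a`, `b`, evaluated in
   direction-vector form so perpendicular and vertical lines stay finite.
6. Per junction, `RoM = |θ_flexion − θ_extension|`, displayed floored to a
   whole degree.

A synthetic spine phantom (`cromkit.phantom`) generates flexion/extension
scenes with *known* per-junction angles, optional boundary jitter and
vertebra dropout, so the whole pipeline can be tested by parameter
recovery. `cromkit.evaluation` provides the validation statistics: IoU
between masks, mean absolute error ± SD per junction, and a two-sided
(Welch) t-test at the 5% level.

## Worked example

Generate a phantom pair and measure it:

```sh
crom phantom --out demo --seed 7
crom measure --flexion demo/flexion.json --extension demo/extension.json --out demo/report
```

which prints

```
subject_id junction  theta_flexion_deg  theta_extension_deg  rom_raw_deg  rom_displayed_deg   status
   subject     C1/2           4.000000            -3.000000     7.000000                  7 measured
   subject     C2/3           4.864325            -4.000000     8.864325                  8 measured
   subject     C3/4           6.986450            -6.000000    12.986450                 12 measured
   subject     C4/5           8.000000            -7.000000    15.000000                 15 measured
   subject     C5/6           6.000000            -5.000000    11.000000                 11 measured
   subject     C6/7           4.000000            -3.005609     7.005609                  7 measured
```

The phantom's programmed flexion angles were (4, 5, 7, 8, 6, 4)° and
extension (−3, −4, −6, −7, −5, −3)°, so every per-pose angle is recovered
to a fraction of a degree and the displayed RoM column is the floored
absolute difference (e.g. C2/3: |4.86 − (−4.00)| = 8.86 → 8). `demo/truth.csv`
holds the ground truth in the same schema for diffing, and
`--overlay DIR` renders the contours, polygons, selected edges and fitted
lines to PNG for visual audit.

The same measurement runs from label masks (`--format mask_png`) and from
any segmenter whose output is converted to the polygon-JSON schema
documented in `cromkit.regions` (a COCO converter is included).

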