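# Methods

## Problem and coordinate conventions

The package measures the cervical range of motion (CRoM): for each junction
C1/2 … C6/7, the angle between reference lines of the two flanking
vertebrae, compared between a full-flexion and a full-extension lateral
radiograph of the same subject. Inputs are per-vertebra segmentation
regions; everything upstream (radiograph acquisition, instance
segmentation) is outside the package, reached only through the `PoseScene`
contract (polygon JSON, label masks, or a COCO converter).

All geometry lives in image coordinates: origin top-left, x rightward,
y **downward**, 0-based pixel indices with polygon vertices on pixel
centers. Angles of undirected lines are folded into (−90°, 90°]. The sign
of an intersegmental angle is positive when the cranial line is rotated
counterclockwise (in standard image display) relative to the caudal line;
since only flexion–extension differences are reported, a global sign flip
is immaterial, and the reported RoM is |θ_flex − θ_ext| with the displayed
value floored to a whole degree (sub-degree values do not affect
diagnosis).

## Chain assembly

Detected regions are sorted by bounding-box `y_min` (ties broken by
`x_min`, with a warning). The `c1`/`c2` classes pin C1/C2; the shared
`c3toc7` class receives consecutive labels after the last pinned label,
starting at C3 when no anchor precedes. Adjacent boxes are a continuous
chain iff `d < 0.5·h(n)` strictly, where `d = y_min(n+1) − y_max(n)` and
`h(n)` is the height of the cranial box; a violated junction is excluded
from measurement.

When continuity fails between two detections, the number of missing bodies
is estimated as `max(1, round((d − g)/(h_med + g)))`, with `h_med` the
median box height and `g` the median gap of the continuous junctions (0 if
none). A naive `round(d/h_med)` over-counts when two or more bodies are
missing, because the span also contains the disc gaps between them; the
corrected form recovers the right count in the one- and two-missing cases.
Labels resolved this way are flagged `inferred_labeling` in the output.

Pose pairing is by resolved label, never by list position; a junction is
measurable only when both flanking vertebrae are present and continuous in
*both* poses, and the report always carries six rows with an explicit
status so unmeasured junctions remain auditable.

## Measurement geometry

Per vertebra: outer contour → convex hull → simple polygon with 3 or 4
vertices. The polygon is a Douglas–Peucker simplification of the closed
hull (anchored at the hull's farthest vertex pair), with the tolerance
found by binary search so the vertex count first reaches 4; 3 is used when
4 is unattainable. C1 is the exception: its ring is triangular, and a
fourth vertex tends to split the long posterior side — the very side the
measurement needs — so the pipeline requests the triangle form for C1.

Edge selection between adjacent vertebrae minimizes the Euclidean distance
between edge midpoints over all edge pairs (ties broken by midpoint-x
proximity). At C1/2, C1 contributes its longest side (posterior arch) and
C2 the side to the right of its lower edge (posterior body); a `facing`
flag flips the left/right comparison for radiographs acquired with the
opposite patient orientation.

Because the 3–4-gon is inscribed in the hull, its edges can sit away from
the true boundary, so each selected edge is refined against the contour.
With the edge normalized to `x1 ≤ x2`, the **upper** band keeps contour
points with `x1 ≤ x ≤ x2` and y between the endpoint y-values; the
**lower** band is the union of two boxes split at the midpoint — the left
box bounded by the y of the left endpoint and the midpoint, the right box
open downward from the right endpoint's y and capped at the contour's own
maximal y (the only principled bound available, and it prevents capturing
the opposite side). The y-bounds carry a margin δ = 2 px (configurable via
`--band-margin`): wide enough for rasterization jitter, narrow enough to
exclude the lateral walls. Two further numerical safeguards:

* the box selection is intersected with a perpendicular-distance cut at δ
  from the edge line — axis-aligned boxes around a tilted edge otherwise
  sweep in lateral-wall points, which can rotate the fit by tens of
  degrees at larger tilts;
* if fewer than two points survive, the fallback band is the boundary run
  nearest the edge: points whose projection falls within the edge span and
  whose perpendicular distance is within δ of the closest such point. The
  same perpendicular band is used directly for edges steeper than 45°
  (the near-vertical C1/C2 lines), where the upper/lower box rules are not
  meaningful; shallower refined edges pick the upper or lower rule from
  whether the edge midpoint lies below the contour centroid.

The band line is a **total least squares** fit (principal axis of the
centered points). Orthogonal regression treats all orientations alike, so
the angle between two fitted lines is invariant under rigid rotation of
the scene — a property y-on-x regression cannot provide — and vertical
lines remain finite via the direction-vector representation. Up to five
trimmed refits (each against the full band) drop points whose
perpendicular residual exceeds 3× the median residual, floored at 0.75 px
so sub-pixel staircase noise is never trimmed; this removes
rounded-corner arcs and stray boundary points and lets the fit escape an
initial estimate dragged toward a displaced polygon corner.

The angle between two lines with slopes a and b follows the tangent
addition theorem, tan θ = (a − b)/(1 + ab), evaluated from direction
vectors: identical where the quotient is defined, exactly 90° at its pole
(perpendicular lines), and finite for vertical lines. Degenerate geometry
in any single junction (collinear contour, empty band) marks only that
junction unmeasured; it never aborts the pose.

## The spine phantom

`generate_phantom` builds both poses of a synthetic lateral cervical spine
in a 512 × 512 raster with exact ground truth:

* C3–C7: convex quadrilateral bodies, default 72 × 40 px; C2: a 72 × 46 px
  body with a triangular cranial protrusion (odontoid, 20 px) placed
  anterior-of-center so the hull approximation keeps the posterior body
  edge; C1: an elongated triangle whose 54 px long side stands in for the
  posterior arch.
* Body tilts realize the programmed per-junction angles exactly: for the
  sub-axial chain, tilt(n+1) = tilt(n) − α(n/n+1), centered so the column
  stays near vertical; the C1 line tilt is set against C2's posterior line
  for the programmed C1/2 angle. Bodies are chained by endplate midpoints —
  the top edge of body n+1 sits one disc gap (11 px) below the bottom edge
  of body n along the mean edge normal — so facing endplates stay aligned
  at any tilt, as in a real column.
* Rounded corners (radius 3 px, shapely buffer), outlines densified to
  2 px spacing, optional seeded radial jitter per vertex
  (`boundary_noise_sd`, the dominant segmentation error mode), and per-pose
  vertebra dropout.
* Default pose angles: flexion (4, 5, 7, 8, 6, 4)°, extension
  (−3, −4, −6, −7, −5, −3)° — per-junction RoM of 7–15°, a plausible adult
  range. Angles must lie in (−25°, 25°) and the stack must fit the image;
  impossible parameter sets raise rather than silently clip.

The phantom emulates region *outlines* only: no radiographic intensities,
cortical texture, spinous processes, osteophytes, or inter-patient shape
variation. Tests passing on it validate the measurement geometry under
boundary error, not the behavior of any particular segmenter on real
radiographs; real-world accuracy is bounded by segmentation quality, which
must be assessed separately (the IoU tooling exists for exactly that).

## Evaluation statistics

IoU is computed pixelwise on rasters (polygon inputs are rasterized at the
scene's native resolution); it is undefined — an error, not 0 — when both
masks are empty. Angle accuracy is summarized as the mean of absolute
errors with its sample SD (ddof = 1), per junction and pooled; unmeasured
entries are excluded pairwise. Group comparison uses a two-sided t-test at
the 5% level; Welch's unequal-variance form is the default as the safer
choice, with `equal_var=True` available for strict pooled-variance
replication. Zero variance in both samples returns p = 1 for equal means
and p = 0 otherwise, by convention.

## Problem sizes in the validation runs

The test suite and `scripts/acceptance.py` use: 1000 random slope pairs
for the angle-formula check; 500 random convex polygon pairs against the
exhaustive edge-selection oracle; 100 random 64 × 64 mask pairs for IoU;
three random-angle phantoms (angles uniform in [−10°, 15°], redrawn if the
stack cannot fit the image) for clean recovery; 20 seeds at 2 px jitter
for noisy recovery; and 2000 null simulations (n = 30 per arm) for t-test
calibration. A full phantom pair measures in well under a second on one
CPU.

## Known limitations

* Endplates are modeled as straight lines; endplate curvature and
  osteophytes are outside the model.
* The C1/2 junction is the least stable measurement (short near-vertical
  lines on an atypical ring), mirroring its status as the hardest junction
  clinically; its noisy-recovery error is roughly twice the sub-axial one.
* Fragmented predictions keep only the largest connected component per
  label; holes are ignored (outer boundary only).
* Label re-anchoring after a mid-chain continuity failure is an estimate;
  such output is explicitly flagged as inferred.
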