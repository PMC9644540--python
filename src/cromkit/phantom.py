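"""Synthetic lateral-cervical-spine phantom with known per-junction angles.

The phantom stacks seven convex vertebral bodies cranial to caudal in a
512 x 512 raster: an elongated triangle for C1 (its long side standing in
for the posterior arch), a body with a cranial protrusion for C2 (odontoid
process), and plain quadrilateral bodies for C3..C7.  Body tilts are chosen
so that the angle between the lower edge of body n and the upper edge of
body n+1 equals the requested intersegmental angle for the pose, which
makes the programmed angles exact ground truth for parameter-recovery
tests.  Optional rounded corners, seeded radial boundary jitter
(segmentation-error surrogate) and per-pose vertebra dropout emulate the
failure modes of an instance segmenter.

The phantom emulates region *outlines* only — no radiographic intensities,
cortical texture, spinous processes or overlapping soft tissue — so tests
that pass on it validate the measurement geometry, not the upstream
segmenter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Polygon

from .errors import PhantomParameterError
from .regions import JUNCTIONS, VERTEBRAE, PoseScene, VertebraRegion, rasterize_scene, seg_class_of
from .assembly import junction_flanks
from .geometry import fold_angle

#: densification step along body outlines, pixels
_SEG_LEN = 2.0


@dataclass(frozen=True)
class PhantomParams:
    """Scene parameters; defaults describe a plausible adult lateral view.

    Angles are per junction (C1/2 .. C6/7), degrees, positive when the
    cranial line is rotated counterclockwise relative to the caudal one in
    image coordinates; flexion and extension take opposite signs so the
    default range of motion per junction is 7-15 degrees.
    """

    image_size: tuple[int, int] = (512, 512)
    body_width: float = 72.0
    body_height: float = 40.0
    c2_body_height: float = 46.0
    junction_gap: float = 11.0  # disc space between adjacent bounding boxes
    angles_flexion: tuple[float, ...] = (4.0, 5.0, 7.0, 8.0, 6.0, 4.0)
    angles_extension: tuple[float, ...] = (-3.0, -4.0, -6.0, -7.0, -5.0, -3.0)
    c1_side_length: float = 54.0  # posterior-arch line of the C1 triangle
    c1_apex_offset: float = 32.0  # anterior reach of the C1 apex
    c2_protrusion: float = 20.0  # odontoid height above the C2 body
    corner_radius: float = 3.0
    boundary_noise_sd: float = 0.0  # radial jitter, pixels
    dropout_flexion: frozenset = frozenset()
    dropout_extension: frozenset = frozenset()
    seed: int = 0

    def validate(self) -> None:
        if self.junction_gap >= 0.5 * self.body_height:
            raise PhantomParameterError(
                "junction_gap must stay below half the body height for a continuous chain"
            )
        for angles in (self.angles_flexion, self.angles_extension):
            if len(angles) != 6:
                raise PhantomParameterError("six per-junction angles required per pose")
            if any(not -25.0 < a < 25.0 for a in angles):
                raise PhantomParameterError("per-junction angles must lie in (-25, 25) degrees")
        for d in (self.dropout_flexion, self.dropout_extension):
            unknown = set(d) - set(VERTEBRAE)
            if unknown:
                raise PhantomParameterError(f"unknown dropout vertebrae {sorted(unknown)}")


@dataclass
class PhantomTruth:
    """Programmed ground truth for parameter-recovery testing."""

    theta_flexion: dict[str, float]
    theta_extension: dict[str, float]
    measurable: dict[str, bool]
    polygons: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def rom(self, junction: str) -> float:
        return abs(self.theta_flexion[junction] - self.theta_extension[junction])


def _rot(deg: float) -> np.ndarray:
    r = math.radians(deg)
    return np.array([[math.cos(r), -math.sin(r)], [math.sin(r), math.cos(r)]])


def _rounded(poly: Polygon, radius: float) -> Polygon:
    if radius <= 0:
        return poly
    shrunk = poly.buffer(-radius, join_style="mitre")
    if shrunk.is_empty or shrunk.geom_type != "Polygon":
        return poly
    return shrunk.buffer(radius, join_style="round", quad_segs=6)


def _exterior(poly: Polygon) -> np.ndarray:
    ring = shapely.segmentize(poly, _SEG_LEN).exterior.coords
    pts = np.asarray(ring, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def _body_tilts(angles: tuple[float, ...]) -> dict[str, float]:
    """Tilts of C2..C7 so adjacent lower/upper edges differ by the programmed
    sub-axial angles, centered to keep the stack near vertical overall."""
    sub = angles[1:]  # C2/3 .. C6/7
    cum = [0.0]
    for a in sub:
        cum.append(cum[-1] - a)
    shift = -(max(cum) + min(cum)) / 2.0
    tilts = {}
    for k, label in enumerate(VERTEBRAE[1:]):  # C2..C7
        tilts[label] = cum[k] + shift
    return tilts


def _build_pose(
    pose: str, angles: tuple[float, ...], dropout: frozenset, params: PhantomParams, rng
) -> tuple[PoseScene, dict[str, np.ndarray]]:
    w, h = params.body_width, params.body_height
    gap = params.junction_gap
    tilts = _body_tilts(angles)

    shapes: dict[str, Polygon] = {}

    def rect(width, height, tilt, center):
        local = np.array(
            [
                [-width / 2, -height / 2],
                [width / 2, -height / 2],
                [width / 2, height / 2],
                [-width / 2, height / 2],
            ]
        )
        return Polygon(local @ _rot(tilt).T + center)

    # C2 body + odontoid protrusion, centered at the origin for now
    t2 = tilts["C2"]
    h2 = params.c2_body_height
    body2 = rect(w, h2, t2, np.zeros(2))
    dens_local = np.array(
        [
            [-0.45 * w, -h2 / 2 + 1.0],
            [-0.10 * w, -h2 / 2 + 1.0],
            [-0.28 * w, -h2 / 2 - params.c2_protrusion],
        ]
    )
    dens = Polygon(dens_local @ _rot(t2).T)
    c2 = body2.union(dens)
    if c2.geom_type != "Polygon":
        raise PhantomParameterError("C2 odontoid union failed to produce a single region")
    shapes["C2"] = c2

    # C3..C7 below: chain by endplate midpoints so the top edge of body n+1
    # sits one disc gap below the bottom edge of body n along the mean edge
    # normal — adjacent endplates face each other at any tilt, as in a real
    # column
    def _down(tilt_deg: float) -> np.ndarray:
        r = math.radians(tilt_deg)
        return np.array([-math.sin(r), math.cos(r)])

    prev = "C2"
    centers = {"C2": np.zeros(2)}
    heights = {"C2": h2}
    for label in VERTEBRAE[2:]:
        tilt = tilts[label]
        bottom_mid = centers[prev] + (heights[prev] / 2.0) * _down(tilts[prev])
        mean_tilt = 0.5 * (tilts[prev] + tilt)
        center = bottom_mid + gap * _down(mean_tilt) + (h / 2.0) * _down(tilt)
        shapes[label] = rect(w, h, tilt, center)
        centers[label] = center
        heights[label] = h
        prev = label

    # C1 triangle above C2: long (posterior-arch) side at the tilt that
    # realizes the programmed C1/2 angle against C2's posterior body line
    t2_line = fold_angle(t2 + 90.0)
    t1_line = fold_angle(t2_line + angles[0])
    u = np.array([math.cos(math.radians(t1_line)), math.sin(math.radians(t1_line))])
    if u[1] < 0:
        u = -u
    perp = np.array([-u[1], u[0]])
    if perp[0] > 0:
        perp = -perp  # apex points anterior (smaller x)
    a = -u * params.c1_side_length / 2.0
    b = u * params.c1_side_length / 2.0
    apex = perp * params.c1_apex_offset
    tri = Polygon([a, b, apex])
    c2_xmin, c2_ymin, c2_xmax, _ = shapes["C2"].bounds
    _, _, _, tri_ymax = tri.bounds
    dy = (c2_ymin - gap) - tri_ymax
    dx = (0.5 * (c2_xmin + c2_xmax) + 0.22 * w) - 0.5 * (tri.bounds[0] + tri.bounds[2])
    shapes["C1"] = shapely.affinity.translate(tri, xoff=dx, yoff=dy)

    # center the stack in the image
    xs = [s.bounds[0] for s in shapes.values()] + [s.bounds[2] for s in shapes.values()]
    ys = [s.bounds[1] for s in shapes.values()] + [s.bounds[3] for s in shapes.values()]
    iw, ih = params.image_size
    off = np.array(
        [iw / 2 - 0.5 * (min(xs) + max(xs)), ih / 2 - 0.5 * (min(ys) + max(ys))]
    )
    margin = 4.0
    if max(xs) - min(xs) > iw - 2 * margin or max(ys) - min(ys) > ih - 2 * margin:
        raise PhantomParameterError("programmed angles produce a stack larger than the image")
    shapes = {
        k: shapely.affinity.translate(s, xoff=off[0], yoff=off[1]) for k, s in shapes.items()
    }
    for i, la in enumerate(VERTEBRAE):
        for lb in VERTEBRAE[i + 1 :]:
            if shapes[la].intersects(shapes[lb]):
                raise PhantomParameterError(f"bodies {la} and {lb} overlap; reduce the angles")

    truth_polys: dict[str, np.ndarray] = {}
    regions = []
    for label in VERTEBRAE:
        r_corner = params.corner_radius if label not in ("C1",) else min(params.corner_radius, 2.0)
        poly = _rounded(shapes[label], r_corner)
        pts = _exterior(poly)
        truth_polys[label] = pts.copy()
        if label in dropout:
            continue
        if params.boundary_noise_sd > 0:
            centroid = pts.mean(axis=0)
            radial = pts - centroid
            norms = np.linalg.norm(radial, axis=1)
            norms[norms == 0] = 1.0
            jitter = rng.normal(0.0, params.boundary_noise_sd, size=len(pts))
            pts = pts + radial / norms[:, None] * jitter[:, None]
        seg = seg_class_of(label)
        regions.append(
            VertebraRegion(
                seg_class=seg,
                contour=pts,
                label=label if seg in ("c1", "c2") else None,
            )
        )
    scene = PoseScene(pose=pose, image_size=params.image_size, regions=regions)
    return scene, truth_polys


def generate_phantom(
    params: Optional[PhantomParams] = None,
) -> tuple[PoseScene, PoseScene, PhantomTruth]:
    """Build the flexion and extension scenes plus their ground truth.

    Deterministic for fixed ``params`` (including ``seed``); masks can be
    obtained with :func:`cromkit.regions.rasterize_scene` after labels are
    resolved.
    """
    params = params or PhantomParams()
    params.validate()
    rng_f = np.random.default_rng(params.seed * 2 + 1)
    rng_e = np.random.default_rng(params.seed * 2 + 2)
    flex, polys_f = _build_pose(
        "flexion", params.angles_flexion, params.dropout_flexion, params, rng_f
    )
    ext, polys_e = _build_pose(
        "extension", params.angles_extension, params.dropout_extension, params, rng_e
    )
    theta_f = dict(zip(JUNCTIONS, params.angles_flexion))
    theta_e = dict(zip(JUNCTIONS, params.angles_extension))
    dropped = set(params.dropout_flexion) | set(params.dropout_extension)
    measurable = {
        j: not (set(junction_flanks(j)) & dropped) for j in JUNCTIONS
    }
    truth = PhantomTruth(
        theta_flexion=theta_f,
        theta_extension=theta_e,
        measurable=measurable,
        polygons={
            **{("flexion", k): v for k, v in polys_f.items()},
            **{("extension", k): v for k, v in polys_e.items()},
        },
    )
    return flex, ext, truth


def truth_table(truth: PhantomTruth) -> pd.DataFrame:
    """Ground truth in the CRoM-report schema, for direct diffing."""
    rows = []
    for j in JUNCTIONS:
        ok = truth.measurable[j]
        rows.append(
            {
                "subject_id": "phantom",
                "junction": j,
                "theta_flexion_deg": truth.theta_flexion[j] if ok else None,
                "theta_extension_deg": truth.theta_extension[j] if ok else None,
                "rom_raw_deg": truth.rom(j) if ok else None,
                "rom_displayed_deg": math.floor(truth.rom(j)) if ok else None,
                "status": "measured" if ok else "unmeasured",
            }
        )
    return pd.DataFrame(rows)
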