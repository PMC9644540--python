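"""Domain types and I/O for labeled vertebra regions.

Coordinate convention: image coordinates with the origin at the top-left
corner, ``x`` increasing rightward (columns) and ``y`` increasing *downward*
(rows).  The cranial-most vertebra (C1) therefore has the smallest
bounding-box ``y``.  Coordinates are 0-based pixel indices; polygon vertices
sit on pixel centers.

Two interchange formats are supported:

``polygon_json``
    The toolkit's canonical format::

        {"pose": "flexion|extension", "image_size": [w, h],
         "regions": [{"class": "c1|c2|c3toc7", "label": "C1".."C7" | null,
                      "polygon": [[x, y], ...]}]}

``mask_png``
    Single-channel PNG; pixel values 1..7 mean C1..C7, 0 is background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import numpy as np
from PIL import Image
from skimage import draw as _skdraw
from skimage import measure as _skmeasure

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical vertebra names, cranial to caudal.
VERTEBRAE = ("C1", "C2", "C3", "C4", "C5", "C6", "C7")

#: Segmentation classes produced by the upstream instance segmenter.
SEG_CLASSES = ("c1", "c2", "c3toc7")

#: Junction names between adjacent vertebrae, cranial to caudal.
JUNCTIONS = ("C1/2", "C2/3", "C3/4", "C4/5", "C5/6", "C6/7")


def seg_class_of(label: str) -> str:
    """Map a vertebra name to its segmentation class (C3..C7 share one)."""
    if label == "C1":
        return "c1"
    if label == "C2":
        return "c2"
    if label in VERTEBRAE:
        return "c3toc7"
    raise ValidationError(f"unknown vertebra label {label!r}")


class Point2D(NamedTuple):
    x: float
    y: float


class BoundingBox(NamedTuple):
    """Tight axis-aligned box; all coordinates in pixels."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


def contour_array(points: Iterable) -> np.ndarray:
    """Validate and normalize a closed contour to an (N, 2) float array.

    The closing vertex is implicit: the last point connects back to the
    first, and an explicit duplicate of the first point is dropped.
    Repeated consecutive points are removed.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("contour must be a sequence of (x, y) pairs")
    if len(arr) >= 2 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if len(arr) >= 2:
        keep = np.ones(len(arr), dtype=bool)
        keep[1:] = ~np.all(np.isclose(arr[1:], arr[:-1]), axis=1)
        arr = arr[keep]
    if len(arr) < 3:
        raise ValidationError("contour needs at least 3 distinct points")
    return arr


def bbox_of(contour: np.ndarray) -> BoundingBox:
    """Elementwise min/max box of a contour (exact)."""
    return BoundingBox(
        float(contour[:, 0].min()),
        float(contour[:, 1].min()),
        float(contour[:, 0].max()),
        float(contour[:, 1].max()),
    )


@dataclass
class VertebraRegion:
    """One segmented vertebra: class, outer contour, optional raster mask.

    ``label`` may be ``None`` on input for ``c3toc7`` instances; label
    resolution is the job of :mod:`cromkit.assembly`.
    """

    seg_class: str
    contour: np.ndarray
    label: Optional[str] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.seg_class not in SEG_CLASSES:
            raise ValidationError(f"unknown segmentation class {self.seg_class!r}")
        if self.label is not None:
            if self.label not in VERTEBRAE:
                raise ValidationError(f"unknown vertebra label {self.label!r}")
            if seg_class_of(self.label) != self.seg_class:
                raise ValidationError(
                    f"label {self.label} inconsistent with class {self.seg_class}"
                )
        self.contour = contour_array(self.contour)

    @property
    def bbox(self) -> BoundingBox:
        return bbox_of(self.contour)

    def with_label(self, label: Optional[str]) -> "VertebraRegion":
        return VertebraRegion(self.seg_class, self.contour, label, self.mask)


@dataclass
class PoseScene:
    """All regions detected in one pose (flexion or extension)."""

    pose: str
    image_size: tuple[int, int]  # (width, height)
    regions: list[VertebraRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pose not in ("flexion", "extension"):
            raise ValidationError(f"pose must be flexion or extension, got {self.pose!r}")
        labels = [r.label for r in self.regions if r.label is not None]
        if len(labels) != len(set(labels)):
            raise ValidationError("two regions share a resolved vertebra label")
        if len(self.regions) > 7:
            raise ValidationError("a cervical scene has at most 7 vertebrae")


# ---------------------------------------------------------------------------
# readers / writers


def _label_for_value(value: int) -> str:
    if not 1 <= value <= 7:
        raise ValidationError(f"mask label value {value} outside 1..7")
    return VERTEBRAE[value - 1]


def _scene_from_mask(arr: np.ndarray, pose: str) -> PoseScene:
    h, w = arr.shape
    values = sorted(int(v) for v in np.unique(arr) if v != 0)
    regions: list[VertebraRegion] = []
    for v in values:
        label = _label_for_value(v)
        binary = arr == v
        comp, ncomp = _skmeasure.label(binary, return_num=True, connectivity=2)
        if ncomp > 1:
            sizes = np.bincount(comp.ravel())[1:]
            biggest = int(np.argmax(sizes)) + 1
            logger.warning(
                "label %s has %d connected components; keeping largest (%d px)",
                label, ncomp, sizes[biggest - 1],
            )
            binary = comp == biggest
        contours = _skmeasure.find_contours(binary.astype(float), 0.5)
        if not contours:
            continue
        outer = max(contours, key=len)  # outer boundary; holes ignored
        xy = np.column_stack([outer[:, 1], outer[:, 0]])  # (row, col) -> (x, y)
        regions.append(
            VertebraRegion(
                seg_class=seg_class_of(label),
                contour=xy,
                label=label,
                mask=binary,
            )
        )
    return PoseScene(pose=pose, image_size=(w, h), regions=regions)


def read_scene(path, format: str, pose: Optional[str] = None) -> PoseScene:
    """Read a :class:`PoseScene` from ``polygon_json`` or ``mask_png``.

    For ``mask_png`` the pose must be given explicitly (a raster carries no
    pose tag); contours are the outer boundary of the largest connected
    component of each label value.  Bounding boxes are always recomputed
    from contours.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "polygon_json":
        try:
            doc = json.loads(path.read_text())
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise FormatError(f"{path} is not valid JSON: {exc}") from exc
        return scene_from_dict(doc)
    if format == "mask_png":
        if pose is None:
            # infer from filename, else default flexion with a warning
            name = path.stem.lower()
            pose = "extension" if "ext" in name else "flexion"
            logger.warning("mask_png carries no pose tag; inferred %r from name", pose)
        try:
            arr = np.asarray(Image.open(path).convert("I"), dtype=np.int32)
        except Exception as exc:  # pillow raises a zoo of types
            raise FormatError(f"cannot read PNG {path}: {exc}") from exc
        bad = np.setdiff1d(np.unique(arr), np.arange(8))
        if bad.size:
            raise ValidationError(f"mask values {bad.tolist()} outside 0..7")
        return _scene_from_mask(arr, pose)
    raise FormatError(f"unknown format {format!r}")


def scene_from_dict(doc: dict) -> PoseScene:
    """Build a scene from an already-parsed polygon_json document."""
    try:
        pose = doc["pose"]
        w, h = doc["image_size"]
        raw = doc["regions"]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"polygon_json missing required key: {exc}") from exc
    regions = []
    for item in raw:
        regions.append(
            VertebraRegion(
                seg_class=item["class"],
                contour=item["polygon"],
                label=item.get("label"),
            )
        )
    return PoseScene(pose=pose, image_size=(int(w), int(h)), regions=regions)


def scene_to_dict(scene: PoseScene) -> dict:
    return {
        "pose": scene.pose,
        "image_size": [int(scene.image_size[0]), int(scene.image_size[1])],
        "regions": [
            {
                "class": r.seg_class,
                "label": r.label,
                "polygon": [[float(x), float(y)] for x, y in r.contour],
            }
            for r in scene.regions
        ],
    }


def rasterize_scene(scene: PoseScene) -> np.ndarray:
    """Rasterize a scene to a label image (0 background, 1..7 = C1..C7).

    Regions must carry resolved labels.  Polygons are clipped to the image;
    a clipped region triggers a warning.
    """
    w, h = scene.image_size
    out = np.zeros((h, w), dtype=np.uint8)
    for r in scene.regions:
        if r.label is None:
            raise ValidationError("cannot rasterize a region without a resolved label")
        value = VERTEBRAE.index(r.label) + 1
        bb = r.bbox
        if bb.x_min < 0 or bb.y_min < 0 or bb.x_max > w - 1 or bb.y_max > h - 1:
            logger.warning("region %s extends beyond the image; rasterization clips it", r.label)
        rr, cc = _skdraw.polygon(r.contour[:, 1], r.contour[:, 0], shape=out.shape)
        out[rr, cc] = value
    return out


def write_scene(scene: PoseScene, path, format: str) -> None:
    """Write a scene; ``polygon_json`` round-trips coordinates bit-exactly."""
    path = Path(path)
    if format == "polygon_json":
        path.write_text(json.dumps(scene_to_dict(scene), indent=1))
        return
    if format == "mask_png":
        Image.fromarray(rasterize_scene(scene), mode="L").save(path)
        return
    raise FormatError(f"unknown format {format!r}")


def coco_to_scene(
    coco: dict, image_id: int, pose: str, category_map: Optional[dict] = None
) -> PoseScene:
    """Convert COCO-style per-instance polygon annotations for one image.

    ``category_map`` maps COCO category id -> segmentation class; by default
    category names are matched against ``c1``/``c2``/``c3toc7``.
    """
    images = {im["id"]: im for im in coco.get("images", [])}
    if image_id not in images:
        raise FormatError(f"image id {image_id} not present in COCO document")
    im = images[image_id]
    if category_map is None:
        category_map = {
            c["id"]: c["name"] for c in coco.get("categories", [])
        }
    regions = []
    for ann in coco.get("annotations", []):
        if ann.get("image_id") != image_id:
            continue
        seg = ann.get("segmentation")
        if not seg:
            continue
        flat = seg[0] if isinstance(seg[0], (list, tuple)) else seg
        poly = np.asarray(flat, dtype=float).reshape(-1, 2)
        cls = category_map.get(ann.get("category_id"))
        if cls not in SEG_CLASSES:
            raise ValidationError(f"COCO category {ann.get('category_id')} not in {SEG_CLASSES}")
        regions.append(VertebraRegion(seg_class=cls, contour=poly))
    return PoseScene(pose=pose, image_size=(int(im["width"]), int(im["height"])), regions=regions)
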