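"""Craniocaudal ordering, chain-continuity validation and label resolution.

Detected regions arrive unordered and, for the shared ``c3toc7`` class,
unlabeled.  Regions are sorted by bounding-box ``y_min`` (cranial first),
the ``c1``/``c2`` classes pin C1 and C2, and remaining instances receive
consecutive labels.  Adjacent boxes form a continuous chain when the
vertical gap between them is less than half the height of the cranial box;
a violated junction is excluded from measurement and label assignment skips
the estimated number of missing bodies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .regions import JUNCTIONS, VERTEBRAE, PoseScene, VertebraRegion

logger = logging.getLogger(__name__)


def junction_name(upper: str, lower: str) -> str:
    """``C3, C4 -> "C3/4"``."""
    return f"{upper}/{lower[1:]}"


def junction_flanks(junction: str) -> tuple[str, str]:
    """``"C3/4" -> ("C3", "C4")``."""
    upper, low = junction.split("/")
    return upper, f"C{low}"


@dataclass
class SpineSequence:
    """Regions of one pose ordered cranial to caudal, with resolved labels."""

    pose: str
    image_size: tuple[int, int]
    ordered: list[VertebraRegion] = field(default_factory=list)
    gaps: set[str] = field(default_factory=set)  # junction names
    inferred_labeling: bool = False  # True when anchors were missing or skipped

    @property
    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.ordered]

    def region(self, label: str) -> Optional[VertebraRegion]:
        for r in self.ordered:
            if r.label == label:
                return r
        return None

    def measurable_junctions(self) -> set[str]:
        """Junctions with both flanking vertebrae present and no continuity gap."""
        present = {r.label for r in self.ordered if r.label is not None}
        out = set()
        for j in JUNCTIONS:
            up, lo = junction_flanks(j)
            if up in present and lo in present and j not in self.gaps:
                out.add(j)
        return out


@dataclass
class ScenePair:
    """Flexion and extension sequences with the junctions measurable in both."""

    flexion: SpineSequence
    extension: SpineSequence
    common_junctions: set[str] = field(default_factory=set)


def _continuity_gap(upper: VertebraRegion, lower: VertebraRegion) -> float:
    """d = y_min(lower box) - y_max(upper box)."""
    return lower.bbox.y_min - upper.bbox.y_max


def _is_continuous(upper: VertebraRegion, lower: VertebraRegion) -> bool:
    # strict inequality: "less than half the height" of the cranial box
    return _continuity_gap(upper, lower) < 0.5 * upper.bbox.height


def order_regions(scene: PoseScene) -> SpineSequence:
    """Sort regions cranially and resolve C1..C7 labels.

    ``c1``/``c2`` instances are pinned to C1/C2; ``c3toc7`` instances get
    consecutive labels after the last pinned label (starting at C3 when no
    anchor precedes them).  When the half-height continuity rule fails
    between consecutive detections, labeling skips the estimated number of
    missing bodies (from the gap size, the median body height and the
    median inter-body gap), so caudal vertebrae keep plausible labels.
    """
    if not scene.regions:
        return SpineSequence(pose=scene.pose, image_size=scene.image_size)
    keys = [(r.bbox.y_min, r.bbox.x_min) for r in scene.regions]
    y_only = [k[0] for k in keys]
    if len(set(y_only)) < len(y_only):
        logger.warning("regions with identical y_min; breaking tie by x_min")
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    regs = [scene.regions[i] for i in order]

    heights = np.array([r.bbox.height for r in regs])
    h_med = float(np.median(heights))
    d_vals = [_continuity_gap(regs[i], regs[i + 1]) for i in range(len(regs) - 1)]
    cont = [d < 0.5 * regs[i].bbox.height for i, d in enumerate(d_vals)]
    cont_gaps = [d for d, c in zip(d_vals, cont) if c and d > 0]
    g_med = float(np.median(cont_gaps)) if cont_gaps else 0.0

    labels: list[Optional[str]] = []
    inferred = False
    next_idx = 0  # index into VERTEBRAE for the next expected label
    for i, r in enumerate(regs):
        if i > 0 and not cont[i - 1]:
            d = d_vals[i - 1]
            missing = max(1, round((d - g_med) / (h_med + g_med)))
            next_idx += missing
            inferred = True
        if r.seg_class == "c1":
            assigned = "C1"
        elif r.seg_class == "c2":
            assigned = "C2"
            if next_idx > 1:
                logger.warning("c2 instance found after label pointer passed C2")
        else:
            idx = max(next_idx, 2)  # c3toc7 labels start at C3
            if idx == 2 and next_idx < 2:
                if not any(l in ("C1", "C2") for l in labels):
                    logger.warning(
                        "no c1/c2 anchors cranial to a c3toc7 instance; assuming C3"
                    )
                    inferred = True
            assigned = VERTEBRAE[idx] if idx < len(VERTEBRAE) else None
            if assigned is None:
                logger.warning("label pointer ran past C7; region left unlabeled")
        if assigned is not None and assigned in labels:
            raise ValidationError(f"label {assigned} resolved twice")
        labels.append(assigned)
        if assigned is not None:
            next_idx = VERTEBRAE.index(assigned) + 1

    seq = SpineSequence(
        pose=scene.pose,
        image_size=scene.image_size,
        ordered=[r.with_label(l) for r, l in zip(regs, labels)],
        inferred_labeling=inferred,
    )
    return check_continuity(seq)


def check_continuity(seq: SpineSequence) -> SpineSequence:
    """Populate ``gaps`` with every junction spanned by a discontinuity.

    A junction between consecutive detections is continuous iff
    ``y_min(n+1) - y_max(n) < 0.5 * height(n)`` (strict).  When the rule
    fails between labels Ca and Cb, every junction from Ca/a+1 through
    Cb-1/b is excluded from measurement.
    """
    gaps: set[str] = set()
    regs = seq.ordered
    for i in range(len(regs) - 1):
        if _is_continuous(regs[i], regs[i + 1]):
            continue
        la, lb = regs[i].label, regs[i + 1].label
        if la is None or lb is None:
            continue
        ia, ib = VERTEBRAE.index(la), VERTEBRAE.index(lb)
        for k in range(ia, ib):
            gaps.add(junction_name(VERTEBRAE[k], VERTEBRAE[k + 1]))
    seq.gaps = gaps
    return seq


def pair_scenes(flexion: SpineSequence, extension: SpineSequence) -> ScenePair:
    """Match the two poses by resolved label and intersect measurable junctions.

    A junction is common when both flanking vertebrae are present and the
    chain is continuous across it in *both* poses; anything else is
    reported unmeasured rather than raising.
    """
    if flexion.pose != "flexion" or extension.pose != "extension":
        raise ValidationError("pair_scenes expects (flexion, extension) sequences")
    common = flexion.measurable_junctions() & extension.measurable_junctions()
    if not common:
        logger.warning("no junction is measurable in both poses")
    return ScenePair(flexion=flexion, extension=extension, common_junctions=common)
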