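"""Debug overlay: contours, hulls, polygons, measurement edges and fitted
lines rendered to a PNG for visual audit of a pose."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .assembly import SpineSequence, junction_flanks
from .errors import CromError
from .geometry import (
    approximate_polygon,
    c1_measurement_line,
    c2_measurement_line,
    convex_hull,
    extract_contour_band,
    refine_edge_band,
    select_measurement_edges,
    fit_line,
)
from .pipeline import MeasureConfig


def render_pose_overlay(
    seq: SpineSequence, path, config: Optional[MeasureConfig] = None
) -> None:
    """Render one pose's measurement geometry to ``path`` (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or MeasureConfig()
    w, h = seq.image_size
    fig, ax = plt.subplots(figsize=(6, 6 * h / max(w, 1)))
    ax.set_xlim(0, w)
    ax.set_ylim(h, 0)  # image convention: y down
    ax.set_aspect("equal")

    polys = {}
    for r in seq.ordered:
        c = np.vstack([r.contour, r.contour[:1]])
        ax.plot(c[:, 0], c[:, 1], color="0.6", lw=0.8)
        if r.label is None:
            continue
        try:
            hull = convex_hull(r.contour)
            poly = approximate_polygon(hull)
        except CromError:
            continue
        polys[r.label] = poly
        p = np.vstack([poly, poly[:1]])
        ax.plot(p[:, 0], p[:, 1], color="tab:blue", lw=1.2)
        ax.annotate(r.label, poly.mean(axis=0), color="tab:blue", fontsize=8)

    for j in sorted(seq.measurable_junctions()):
        up, lo = junction_flanks(j)
        if up not in polys or lo not in polys:
            continue
        try:
            if j == "C1/2":
                e1 = c1_measurement_line(polys[up])
                e2 = c2_measurement_line(polys[lo], facing=config.facing)
                bands = [
                    refine_edge_band(seq.region(up).contour, e1, config.band_margin),
                    refine_edge_band(seq.region(lo).contour, e2, config.band_margin),
                ]
            else:
                e1, e2 = select_measurement_edges(polys[up], polys[lo])
                bands = [
                    extract_contour_band(seq.region(up).contour, e1, "lower", config.band_margin),
                    extract_contour_band(seq.region(lo).contour, e2, "upper", config.band_margin),
                ]
        except CromError:
            continue
        for e, band in zip((e1, e2), bands):
            ax.plot([e.x1, e.x2], [e.y1, e.y2], color="tab:orange", lw=1.5)
            ax.plot(band.verts_x, band.verts_y, ".", color="tab:red", ms=2)
            try:
                line = fit_line(band)
            except CromError:
                continue
            xm, ym = e.midpoint
            dx, dy = line.direction
            half = 0.7 * e.length
            ax.plot(
                [xm - half * dx, xm + half * dx],
                [ym - half * dy, ym + half * dy],
                color="tab:green",
                lw=1.0,
            )
    ax.set_title(f"{seq.pose} overlay")
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)
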