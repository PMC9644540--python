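"""End-to-end orchestration: scenes -> per-junction angles -> CRoM report.

For each pose, every continuous junction gets an intersegmental angle:

* C1/2 — angle between the longest side of the C1 triangle approximation
  (posterior arch) and the side to the right of the lower edge of C2
  (posterior vertebral body), each refined against the contour.
* C2/3 .. C6/7 — the facing-edge pair between the two polygon
  approximations (closest midpoints), refined to contour bands (lower edge
  of the cranial body, upper edge of the caudal one), a least-squares line
  through each band, and the angle between the two lines.

The range of motion per junction is the absolute difference between the
flexion and extension angles; the displayed value is floored to a whole
degree, since fractional degrees do not affect diagnosis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import __version__
from .assembly import ScenePair, SpineSequence, junction_flanks
from .errors import DegenerateGeometryError, UnmeasurableEdgeError
from .geometry import (
    DEFAULT_BAND_MARGIN,
    angle_between,
    approximate_polygon,
    c1_measurement_line,
    c2_measurement_line,
    convex_hull,
    extract_contour_band,
    fit_line,
    refine_edge_band,
    select_measurement_edges,
)
from .regions import JUNCTIONS

logger = logging.getLogger(__name__)

REPORT_COLUMNS = (
    "subject_id",
    "junction",
    "theta_flexion_deg",
    "theta_extension_deg",
    "rom_raw_deg",
    "rom_displayed_deg",
    "status",
)


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable measurement parameters."""

    band_margin: float = DEFAULT_BAND_MARGIN  # pixels
    facing: str = "left"  # patient orientation; flips the C2 "right" side


@dataclass
class JunctionMeasurement:
    junction: str
    theta_flexion: Optional[float] = None  # degrees
    theta_extension: Optional[float] = None
    status: str = "unmeasured"

    @property
    def rom_raw(self) -> Optional[float]:
        if self.status != "measured":
            return None
        return abs(self.theta_flexion - self.theta_extension)

    @property
    def rom_displayed(self) -> Optional[int]:
        r = self.rom_raw
        return None if r is None else math.floor(r)


@dataclass
class CRoMReport:
    """Always six junction rows; unmeasured junctions carry no angles."""

    subject_id: str
    measurements: list[JunctionMeasurement]
    provenance: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "junction": m.junction,
                    "theta_flexion_deg": m.theta_flexion,
                    "theta_extension_deg": m.theta_extension,
                    "rom_raw_deg": m.rom_raw,
                    "rom_displayed_deg": m.rom_displayed,
                    "status": m.status,
                }
            )
        return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["rom_displayed_deg"] = df["rom_displayed_deg"].astype("Int64")
        df.to_csv(path, index=False, float_format="%.6f")

    def to_json_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "provenance": self.provenance,
            "measurements": [
                {
                    "junction": m.junction,
                    "theta_flexion_deg": m.theta_flexion,
                    "theta_extension_deg": m.theta_extension,
                    "rom_raw_deg": m.rom_raw,
                    "rom_displayed_deg": m.rom_displayed,
                    "status": m.status,
                }
                for m in self.measurements
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)


def _junction_angle(
    seq: SpineSequence, junction: str, polys: dict, config: MeasureConfig
) -> float:
    """Angle for one junction; raises on degenerate geometry."""
    up_label, lo_label = junction_flanks(junction)
    up = seq.region(up_label)
    lo = seq.region(lo_label)
    assert up is not None and lo is not None
    if junction == "C1/2":
        e1 = c1_measurement_line(polys[up_label])
        e2 = c2_measurement_line(polys[lo_label], facing=config.facing)
        band1 = refine_edge_band(up.contour, e1, config.band_margin)
        band2 = refine_edge_band(lo.contour, e2, config.band_margin)
    else:
        e1, e2 = select_measurement_edges(polys[up_label], polys[lo_label])
        band1 = extract_contour_band(up.contour, e1, "lower", config.band_margin)
        band2 = extract_contour_band(lo.contour, e2, "upper", config.band_margin)
    return angle_between(fit_line(band1), fit_line(band2))


def measure_pose(
    seq: SpineSequence, config: Optional[MeasureConfig] = None
) -> dict[str, float]:
    """Per-junction intersegmental angles (degrees) for one pose.

    Junctions excluded by the continuity check or a missing flank are
    absent from the mapping; a degenerate-geometry failure inside a single
    junction marks only that junction unmeasured.
    """
    config = config or MeasureConfig()
    polys: dict[str, object] = {}
    for r in seq.ordered:
        if r.label is None:
            continue
        try:
            # C1 is a triangular ring: the triangle form keeps its long
            # posterior side intact; all other bodies prefer 4 vertices
            mv = 3 if r.label == "C1" else 4
            polys[r.label] = approximate_polygon(convex_hull(r.contour), max_vertices=mv)
        except DegenerateGeometryError as exc:
            logger.warning("vertebra %s: degenerate geometry (%s)", r.label, exc)
    out: dict[str, float] = {}
    for j in seq.measurable_junctions():
        up, lo = junction_flanks(j)
        if up not in polys or lo not in polys:
            continue
        try:
            out[j] = _junction_angle(seq, j, polys, config)
        except (DegenerateGeometryError, UnmeasurableEdgeError) as exc:
            logger.warning("junction %s unmeasured: %s", j, exc)
    return out


def measure_crom(
    pair: ScenePair,
    config: Optional[MeasureConfig] = None,
    subject_id: str = "subject",
    provenance: Optional[dict] = None,
) -> CRoMReport:
    """Six-row CRoM report for a flexion/extension pair."""
    config = config or MeasureConfig()
    th_f = measure_pose(pair.flexion, config)
    th_e = measure_pose(pair.extension, config)
    measurements = []
    for j in JUNCTIONS:
        m = JunctionMeasurement(junction=j)
        if j in pair.common_junctions and j in th_f and j in th_e:
            m.theta_flexion = th_f[j]
            m.theta_extension = th_e[j]
            m.status = "measured"
        measurements.append(m)
    prov = dict(provenance or {})
    cfg_digest = hashlib.sha256(
        json.dumps({"band_margin": config.band_margin, "facing": config.facing}).encode()
    ).hexdigest()[:12]
    prov.setdefault("config_digest", cfg_digest)
    prov.setdefault("software_version", __version__)
    return CRoMReport(subject_id=subject_id, measurements=measurements, provenance=prov)
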