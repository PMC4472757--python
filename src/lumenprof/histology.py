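"""Section-level lumen morphometry for histology.

Embedded and sectioned vessels are often compressed, so planimetric area of
the traced lumen contour underestimates the true cross-section.  The rule
implemented here therefore derives the lumen from the contour *perimeter*
under a circular assumption (d = P/pi, A = P^2/(4 pi)), which is invariant
under perimeter-preserving compression.  For plaque-bearing sections the
contour is the inner boundary of the tunica media, and the annotated plaque
area is subtracted from the media circle to estimate the residual lumen.

Contours are simple closed polygons; vertex units (um or mm) are declared at
load time and converted to mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .profiling import LumenProfile

__all__ = [
    "SectionContour",
    "SectionMeasurement",
    "polygon_metrics",
    "lumen_from_perimeter",
    "lumen_with_plaque",
    "measure_section",
    "histology_profile",
    "contour_to_wkt",
    "contour_from_wkt",
]

_UNIT_TO_MM = {"mm": 1.0, "um": 1e-3, "µm": 1e-3}


@dataclass
class SectionContour:
    """One traced boundary on a histology section.

    ``role`` is ``"lumen"`` (lumen-intima boundary of a healthy section) or
    ``"inner_media"`` (inner boundary of the tunica media of a plaque-bearing
    section, to be combined with ``plaque_area_mm2``).
    """

    vertices: np.ndarray            # (n, 2), closed polygon (first != last ok)
    position_mm: float
    role: str = "lumen"
    plaque_area_mm2: float = 0.0
    vessel_id: str = "v0"
    units: str = "mm"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs at least three 2-D vertices")
        if np.array_equal(v[0], v[-1]):
            v = v[:-1]
        if self.units not in _UNIT_TO_MM:
            raise ValueError(f"unknown contour units {self.units!r} (use 'mm' or 'um')")
        self.vertices = v * _UNIT_TO_MM[self.units]
        self.units = "mm"
        if self.role not in ("lumen", "inner_media"):
            raise ValueError(f"role must be 'lumen' or 'inner_media', got {self.role!r}")
        if self.plaque_area_mm2 < 0:
            raise ValueError("plaque_area_mm2 must be >= 0")


@dataclass
class SectionMeasurement:
    """Morphometry of one section plus the derived circular-equivalent lumen."""

    perimeter: float         # mm
    planimetric_area: float  # mm^2, shoelace
    circ_diameter: float     # mm, P/pi
    lumen_area: float        # mm^2
    used_plaque_rule: bool
    position_mm: float = 0.0
    vessel_id: str = "v0"

    def to_dict(self) -> dict:
        return {
            "vessel_id": self.vessel_id,
            "position_mm": self.position_mm,
            "perimeter_mm": self.perimeter,
            "planimetric_area_mm2": self.planimetric_area,
            "circ_diameter_mm": self.circ_diameter,
            "lumen_area_mm2": self.lumen_area,
            "used_plaque_rule": self.used_plaque_rule,
        }


def polygon_metrics(contour: SectionContour | np.ndarray) -> tuple[float, float]:
    """Perimeter (edge-length sum) and planimetric area (shoelace, absolute).

    Self-intersecting polygons are rejected; a degenerate zero-area polygon
    measures with a warning.
    """
    v = contour.vertices if isinstance(contour, SectionContour) else np.asarray(contour, dtype=float)
    if np.array_equal(v[0], v[-1]):
        v = v[:-1]
    if len(v) < 3:
        raise ValueError("polygon needs at least three vertices")
    closed = np.vstack([v, v[:1]])
    perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    if area == 0.0:
        # a zero-area ring always retraces itself; warn rather than reject
        warnings.warn("degenerate contour with zero area", UserWarning, stacklevel=2)
        return perimeter, area
    if not LineString(closed).is_simple:
        raise ValueError("self-intersecting contour: fix the tracing before measuring")
    return perimeter, area


def lumen_from_perimeter(perimeter: float) -> tuple[float, float]:
    """Circular-equivalent diameter and area from a lumen perimeter.

    d = P/pi and A = P^2/(4 pi).  By the isoperimetric inequality A is an
    upper bound on the planimetric area of any contour with that perimeter,
    with equality only for a circle; for a compressed (perimeter-preserving)
    section it recovers the uncompressed circular area.
    """
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return perimeter / np.pi, perimeter**2 / (4.0 * np.pi)


def lumen_with_plaque(media_perimeter: float, plaque_area: float) -> float:
    """Lumen area of a plaque-bearing section.

    The inner-media perimeter defines the pre-plaque circular lumen; the
    annotated plaque area is subtracted.  A plaque exceeding the circle
    clamps the result to 0 with a near-occlusion warning.
    """
    if media_perimeter <= 0:
        raise ValueError("media perimeter must be positive")
    if plaque_area < 0:
        raise ValueError("plaque_area must be >= 0")
    _, circle_area = lumen_from_perimeter(media_perimeter)
    lumen = circle_area - plaque_area
    if lumen < 0:
        warnings.warn(
            f"plaque area {plaque_area:.4g} mm^2 exceeds the media circle "
            f"({circle_area:.4g} mm^2); lumen clamped to 0 (near-occlusion)",
            UserWarning,
            stacklevel=2,
        )
        lumen = 0.0
    return float(lumen)


def measure_section(contour: SectionContour) -> SectionMeasurement:
    """Full morphometry of one section, dispatching on the contour role."""
    perimeter, plan_area = polygon_metrics(contour)
    circ_diameter, circle_area = lumen_from_perimeter(perimeter)
    if contour.role == "inner_media":
        lumen = lumen_with_plaque(perimeter, contour.plaque_area_mm2)
        used_plaque = True
    else:
        lumen = circle_area
        used_plaque = False
    return SectionMeasurement(
        perimeter=perimeter,
        planimetric_area=plan_area,
        circ_diameter=circ_diameter,
        lumen_area=lumen,
        used_plaque_rule=used_plaque,
        position_mm=contour.position_mm,
        vessel_id=contour.vessel_id,
    )


def histology_profile(
    measurements: list,
    n_segments: int = 9,
    *,
    vessel_id: str | None = None,
    side: str = "LCCA",
    timepoint_days: int | None = None,
) -> LumenProfile:
    """Assemble section measurements into a segment profile.

    With exactly ``n_segments`` sections, section k maps to segment k
    (index-matched, the common case of nine 500-um sections).  Otherwise the
    section positions are normalized to [0, 1] and assigned to the nearest of
    ``n_segments`` equidistant bin centres; a segment left without sections
    is reported as NaN with a warning.  Duplicate positions are an error.
    """
    if not measurements:
        raise ValueError("no section measurements given")
    ms = sorted(measurements, key=lambda m: m.position_mm)
    pos = np.array([m.position_mm for m in ms])
    if len(np.unique(pos)) != len(pos):
        raise ValueError("duplicate section positions")
    areas = np.array([m.lumen_area for m in ms])
    if vessel_id is None:
        vessel_id = ms[0].vessel_id

    if len(ms) == n_segments:
        seg_area = areas.copy()
    else:
        seg_area = np.full(n_segments, np.nan)
        span = pos[-1] - pos[0]
        t = (pos - pos[0]) / span if span > 0 else np.zeros_like(pos)
        centers = (np.arange(n_segments) + 0.5) / n_segments
        assigned = np.abs(t[:, None] - centers[None, :]).argmin(axis=1)
        for i in range(n_segments):
            sel = areas[assigned == i]
            if sel.size:
                seg_area[i] = sel.mean()
        if np.isnan(seg_area).any():
            warnings.warn(
                f"{int(np.isnan(seg_area).sum())} of {n_segments} segments "
                "received no section; reported as NaN",
                UserWarning,
                stacklevel=2,
            )
    seg_diam = np.sqrt(4.0 * seg_area / np.pi)
    return LumenProfile(
        mean_diameter=seg_diam,
        area=seg_area,
        vessel_id=vessel_id,
        side=side,
        timepoint_days=timepoint_days,
        n_segments=n_segments,
    )


# ---------------------------------------------------------------------------
# CSV plumbing: contours as WKT polygon strings


def contour_to_wkt(vertices: np.ndarray) -> str:
    v = np.asarray(vertices, dtype=float)
    if not np.array_equal(v[0], v[-1]):
        v = np.vstack([v, v[:1]])
    return Polygon(v).wkt


def contour_from_wkt(wkt: str) -> np.ndarray:
    from shapely import from_wkt

    poly = from_wkt(wkt)
    return np.asarray(poly.exterior.coords)[:-1]


def sections_to_frame(contours: list) -> pd.DataFrame:
    """Serializable table of section contours (vertices as WKT polygons)."""
    return pd.DataFrame(
        {
            "section_id": np.arange(len(contours)),
            "vessel_id": [c.vessel_id for c in contours],
            "position_mm": [c.position_mm for c in contours],
            "role": [c.role for c in contours],
            "polygon": [contour_to_wkt(c.vertices) for c in contours],
            "plaque_area_mm2": [c.plaque_area_mm2 for c in contours],
        }
    )


def sections_from_frame(frame: pd.DataFrame, units: str = "mm") -> list:
    out = []
    for _, row in frame.iterrows():
        out.append(
            SectionContour(
                vertices=contour_from_wkt(row["polygon"]),
                position_mm=float(row["position_mm"]),
                role=str(row["role"]),
                plaque_area_mm2=float(row.get("plaque_area_mm2", 0.0)),
                vessel_id=str(row["vessel_id"]),
                units=units,
            )
        )
    return out
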