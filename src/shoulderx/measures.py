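"""The three radiographic shoulder measurements and their risk bands.

* **CSA** (critical shoulder angle): angle at the inferior glenoid pole I
  between the glenoid line I->G and the line I->A to the lateral acromion
  edge.  Elevated CSA is associated with rotator-cuff pathology.
* **AI** (acromion index): ratio of the perpendicular distance of A to the
  glenoid line G-I over the perpendicular distance of the lateral humeral
  surface H to the same line.  The perpendicular ("glenoid plane") reading
  is used; a point-to-point reading would leave the glenoid reference point
  undefined.
* **LAA** (lateral acromion angle, as defined here): angle at the glenoid
  midpoint V = midpoint(G, I) between V->A and V->H.  Note this construction
  differs from the classical undersurface-based LAA.

All three quantities are invariant under translation, uniform scaling,
rotation and reflection of the landmark set, so no physical calibration is
needed.

Risk bands follow the conventional clinical cut-offs: CSA <30 (low risk),
30-35 (moderate), >=35 (high); LAA <45, 45-55 inclusive (normal), >55;
AI <0.7, 0.7-1, >=1.  Note the LAA middle band is closed at both ends while
the CSA and AI middle bands are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidGeometryError, MeasurementError
from .geometry import (
    COINCIDENCE_TOL,
    Line,
    Point,
    angle_at_vertex,
    midpoint,
    perpendicular_distance,
)
from .landmarks import (
    DEFAULT_MIN_REGION_PIXELS,
    LandmarkSet,
    RegionMasks,
    extract_landmarks,
    infer_vertical_orientation,
    largest_component,
)

#: Band labels per measure, in increasing-value order.
RISK_BANDS: dict[str, tuple[str, str, str]] = {
    "CSA": ("<30", "30 ≤ CSA < 35", "≥35"),
    "LAA": ("<45", "45 ≤ LAA ≤ 55", ">55"),
    "AI": ("<0.7", "0.7 ≤ AI < 1", "≥1"),
}

MEASURE_NAMES = tuple(RISK_BANDS)


def compute_csa(lm: LandmarkSet) -> float:
    """Critical shoulder angle in degrees: angle at I between I->G and I->A."""
    return angle_at_vertex(vertex=lm.I, p1=lm.G, p2=lm.A)


def compute_ai(lm: LandmarkSet) -> float:
    """Acromion index: lateral extent of A over lateral extent of H w.r.t. G-I."""
    glenoid_line = Line(lm.G, lm.I)
    d_h = perpendicular_distance(lm.H, glenoid_line)
    if d_h <= COINCIDENCE_TOL:
        raise InvalidGeometryError("humeral landmark lies on the glenoid line; AI undefined")
    return perpendicular_distance(lm.A, glenoid_line) / d_h


def compute_laa(lm: LandmarkSet) -> float:
    """Lateral acromion angle in degrees at the glenoid midpoint V = mid(G, I)."""
    return angle_at_vertex(vertex=midpoint(lm.G, lm.I), p1=lm.A, p2=lm.H)


def classify_risk(measure_name: str, value: float) -> str:
    """Map a measurement value to its risk band label.

    The three band partitions cover every finite positive value exactly once:
    CSA: <30 | [30, 35) | >=35; LAA: <45 | [45, 55] | >55;
    AI: <0.7 | [0.7, 1) | >=1.
    """
    if measure_name not in RISK_BANDS:
        raise ValueError(f"unknown measure {measure_name!r}; expected one of {MEASURE_NAMES}")
    low, mid, high = RISK_BANDS[measure_name]
    if measure_name == "CSA":
        return low if value < 30 else (mid if value < 35 else high)
    if measure_name == "LAA":
        return low if value < 45 else (mid if value <= 55 else high)
    return low if value < 0.7 else (mid if value < 1 else high)


@dataclass
class MeasurementRecord:
    """One study's measurements, bands, landmarks and provenance."""

    source_id: str
    csa: float
    ai: float
    laa: float
    landmarks: LandmarkSet
    csa_band: str = field(init=False)
    ai_band: str = field(init=False)
    laa_band: str = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.csa < 180:
            raise ValueError(f"CSA {self.csa} outside (0, 180)")
        if not 0 < self.laa < 180:
            raise ValueError(f"LAA {self.laa} outside (0, 180)")
        if not self.ai > 0:
            raise ValueError(f"AI {self.ai} must be positive")
        self.csa_band = classify_risk("CSA", self.csa)
        self.ai_band = classify_risk("AI", self.ai)
        self.laa_band = classify_risk("LAA", self.laa)

    #: CSV column order used by the interface module.
    CSV_COLUMNS = (
        "source_id",
        "csa_deg",
        "ai_ratio",
        "laa_deg",
        "csa_band",
        "laa_band",
        "ai_band",
        "Gx",
        "Gy",
        "Ix",
        "Iy",
        "Ax",
        "Ay",
        "Hx",
        "Hy",
        "lateral_sign",
    )

    def to_row(self) -> dict:
        lm = self.landmarks
        return {
            "source_id": self.source_id,
            "csa_deg": self.csa,
            "ai_ratio": self.ai,
            "laa_deg": self.laa,
            "csa_band": self.csa_band,
            "laa_band": self.laa_band,
            "ai_band": self.ai_band,
            "Gx": lm.G.x,
            "Gy": lm.G.y,
            "Ix": lm.I.x,
            "Iy": lm.I.y,
            "Ax": lm.A.x,
            "Ay": lm.A.y,
            "Hx": lm.H.x,
            "Hy": lm.H.y,
            "lateral_sign": lm.lateral_sign,
        }


def measure_landmarks(lm: LandmarkSet, source_id: str = "") -> MeasurementRecord:
    """Measurements straight from a landmark set (no raster involved)."""
    return MeasurementRecord(
        source_id=source_id,
        csa=compute_csa(lm),
        ai=compute_ai(lm),
        laa=compute_laa(lm),
        landmarks=lm,
    )


def measure_study(
    regions: RegionMasks,
    source_id: str = "",
    min_region_pixels: int = DEFAULT_MIN_REGION_PIXELS,
) -> MeasurementRecord:
    """Full pipeline for one study: masks -> landmarks -> CSA/AI/LAA + bands.

    Vertically flipped images (acromion below the humeral head) are
    normalized by flipping the masks top-to-bottom before landmark
    extraction, so the superior-up assumption of the landmark rules holds;
    the recorded landmarks then live in the normalized frame.  All three
    measurements are reflection-invariant, so the values are unaffected.

    Landmark errors are re-raised as :class:`MeasurementError` carrying the
    study's ``source_id`` and the underlying cause (which names the
    offending region).
    """
    try:
        if (
            infer_vertical_orientation(
                largest_component(regions.acromion), largest_component(regions.humerus)
            )
            < 0
        ):
            regions = regions.mirrored_y()
        lm = extract_landmarks(regions, min_region_pixels=min_region_pixels)
        return measure_landmarks(lm, source_id=source_id)
    except MeasurementError:
        raise
    except Exception as exc:
        raise MeasurementError(source_id, exc) from exc
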