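"""Anatomical landmark extraction from per-class binary masks.

Given binary rasters of the acromion, glenoid and humerus on a shared grid,
this module locates the four landmarks the measurements are built on:

* ``G`` — superior pole of the glenoid rim,
* ``I`` — inferior pole of the glenoid rim,
* ``A`` — lateral-most point of the acromion (inferolateral corner on ties),
* ``H`` — lateral-most point of the humeral head (superior on ties),

plus a laterality sign (+1 when anatomical lateral points toward +x, -1 for
mirrored views) inferred from the humerus/glenoid centroid order: in an AP
shoulder view the humeral head lies lateral to the glenoid.

Only the largest 4-connected component of each class is used — instance
segmenters occasionally leak a few speckle pixels of one bone into another
region, and one bone per class per image is the anatomical ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import (
    AmbiguousLateralityError,
    DegenerateGlenoidError,
    EmptyRegionError,
    InvalidGeometryError,
)
from .geometry import Point

DEFAULT_MIN_REGION_PIXELS = 10


def _as_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"{name} must be strictly binary, found values {uniq[:5]}")
        arr = arr.astype(bool)
    return arr


@dataclass
class RegionMasks:
    """Three per-class binary rasters on a shared pixel grid."""

    acromion: np.ndarray
    glenoid: np.ndarray
    humerus: np.ndarray

    def __post_init__(self) -> None:
        self.acromion = _as_binary(self.acromion, "acromion")
        self.glenoid = _as_binary(self.glenoid, "glenoid")
        self.humerus = _as_binary(self.humerus, "humerus")
        if not (self.acromion.shape == self.glenoid.shape == self.humerus.shape):
            raise ValueError("all three region masks must share the same shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.acromion.shape

    @property
    def height(self) -> int:
        return self.acromion.shape[0]

    @property
    def width(self) -> int:
        return self.acromion.shape[1]

    def items(self):
        yield "acromion", self.acromion
        yield "glenoid", self.glenoid
        yield "humerus", self.humerus

    def mirrored_x(self) -> "RegionMasks":
        """Flip left/right (mirror about the vertical image axis)."""
        return RegionMasks(
            acromion=self.acromion[:, ::-1].copy(),
            glenoid=self.glenoid[:, ::-1].copy(),
            humerus=self.humerus[:, ::-1].copy(),
        )

    def mirrored_y(self) -> "RegionMasks":
        """Flip top/bottom (mirror about the horizontal image axis)."""
        return RegionMasks(
            acromion=self.acromion[::-1, :].copy(),
            glenoid=self.glenoid[::-1, :].copy(),
            humerus=self.humerus[::-1, :].copy(),
        )


@dataclass(frozen=True)
class LandmarkSet:
    """The four measurement landmarks plus the lateral direction sign."""

    G: Point
    I: Point
    A: Point
    H: Point
    lateral_sign: int

    def __post_init__(self) -> None:
        if self.lateral_sign not in (+1, -1):
            raise ValueError("lateral_sign must be +1 or -1")
        if not self.G.y < self.I.y:
            raise InvalidGeometryError("superior glenoid pole G must lie above I (smaller y)")
        if (self.A.x - self.G.x) * self.lateral_sign <= 0:
            raise InvalidGeometryError("acromion landmark A must lie lateral to the glenoid")

    def mirrored_x(self, width: float) -> "LandmarkSet":
        """Landmarks of the x-mirrored image (columns 0..width-1 reversed)."""
        m = lambda p: Point(width - 1 - p.x, p.y)
        return LandmarkSet(m(self.G), m(self.I), m(self.A), m(self.H), -self.lateral_sign)


def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary of a binary mask: foreground pixels with a background 4-neighbor.

    Off-image counts as background, so pixels on the raster border are
    boundary.  Returns a boolean raster of the same shape.
    """
    arr = _as_binary(mask)
    if not arr.any():
        raise EmptyRegionError("mask", "no foreground pixels")
    padded = np.pad(arr, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return arr & ~interior


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 4-connected foreground component (empty masks pass through)."""
    arr = _as_binary(mask)
    labels, n = ndimage.label(arr)  # default structure = 4-connectivity
    if n <= 1:
        return arr
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def infer_laterality(glenoid: np.ndarray, humerus: np.ndarray) -> int:
    """+1 if the humerus centroid is right of the glenoid centroid, else -1.

    Raises :class:`AmbiguousLateralityError` when the centroids are within
    1 px of each other in x.
    """
    g = _as_binary(glenoid, "glenoid")
    h = _as_binary(humerus, "humerus")
    if not g.any():
        raise EmptyRegionError("glenoid")
    if not h.any():
        raise EmptyRegionError("humerus")
    gx = np.argwhere(g)[:, 1].mean()
    hx = np.argwhere(h)[:, 1].mean()
    if abs(hx - gx) < 1.0:
        raise AmbiguousLateralityError(
            f"glenoid and humerus centroids nearly coincide in x ({gx:.2f} vs {hx:.2f})"
        )
    return +1 if hx > gx else -1


def infer_vertical_orientation(acromion: np.ndarray, humerus: np.ndarray) -> int:
    """+1 when superior anatomy is up (acromion centroid above the humeral
    head centroid, i.e. at smaller y), -1 for vertically flipped images.

    Raises :class:`AmbiguousLateralityError` when the centroids are within
    1 px of each other in y.
    """
    a = _as_binary(acromion, "acromion")
    h = _as_binary(humerus, "humerus")
    if not a.any():
        raise EmptyRegionError("acromion")
    if not h.any():
        raise EmptyRegionError("humerus")
    ay = np.argwhere(a)[:, 0].mean()
    hy = np.argwhere(h)[:, 0].mean()
    if abs(hy - ay) < 1.0:
        raise AmbiguousLateralityError(
            f"acromion and humerus centroids nearly coincide in y ({ay:.2f} vs {hy:.2f})"
        )
    return +1 if ay < hy else -1


def find_glenoid_poles(glenoid: np.ndarray, lateral_sign: int) -> tuple[Point, Point]:
    """Superior (G) and inferior (I) glenoid poles from the boundary pixels.

    G is the boundary pixel of minimal row, I of maximal row; ties broken
    toward anatomical lateral.
    """
    boundary = extract_boundary(glenoid)
    ys, xs = np.nonzero(boundary)
    if ys.max() - ys.min() + 1 <= 2:
        raise DegenerateGlenoidError(
            f"glenoid spans only {ys.max() - ys.min() + 1} rows; cannot define poles"
        )

    def pole(row: int) -> Point:
        cols = xs[ys == row]
        x = cols.max() if lateral_sign > 0 else cols.min()
        return Point(float(x), float(row))

    return pole(int(ys.min())), pole(int(ys.max()))


def find_lateral_extreme(
    mask: np.ndarray, lateral_sign: int, tie_break: Literal["superior", "inferior"]
) -> Point:
    """Boundary pixel with extreme x in the lateral direction.

    Among equally lateral pixels the most inferior one is chosen for the
    acromion (the clinically relevant inferolateral corner) and the most
    superior one for the humeral head.
    """
    if tie_break not in ("superior", "inferior"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    boundary = extract_boundary(mask)
    ys, xs = np.nonzero(boundary)
    x_ext = xs.max() if lateral_sign > 0 else xs.min()
    rows = ys[xs == x_ext]
    y = rows.max() if tie_break == "inferior" else rows.min()
    return Point(float(x_ext), float(y))


def extract_landmarks(
    regions: RegionMasks, min_region_pixels: int = DEFAULT_MIN_REGION_PIXELS
) -> LandmarkSet:
    """Full landmark extraction: laterality, glenoid poles, lateral extremes.

    Each class is reduced to its largest 4-connected component and must
    retain at least ``min_region_pixels`` foreground pixels.  Errors name
    the offending region.
    """
    cleaned = {}
    for name, mask in regions.items():
        comp = largest_component(mask)
        n = int(comp.sum())
        if n < min_region_pixels:
            raise EmptyRegionError(name, f"{n} px < required {min_region_pixels}")
        cleaned[name] = comp

    lateral_sign = infer_laterality(cleaned["glenoid"], cleaned["humerus"])
    G, I = find_glenoid_poles(cleaned["glenoid"], lateral_sign)
    A = find_lateral_extreme(cleaned["acromion"], lateral_sign, tie_break="inferior")
    H = find_lateral_extreme(cleaned["humerus"], lateral_sign, tie_break="superior")
    return LandmarkSet(G=G, I=I, A=A, H=H, lateral_sign=lateral_sign)
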