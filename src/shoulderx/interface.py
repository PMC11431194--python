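"""File formats and the segmentation-backend contract.

Disk formats:

* **Label maps** — single-channel 8-bit PNG with the fixed encoding
  0 = background, 1 = acromion, 2 = glenoid, 3 = humerus.  Any other value
  is rejected.
* **Polygon text** — one polygon per line, ``class_id x1 y1 x2 y2 ...``
  with coordinates normalized to [0, 1] (x then y) and 0-based class ids
  0 = acromion, 1 = glenoid, 2 = humerus; the native text dialect of
  instance-segmentation exporters.  Polygons are filled by even-odd pixel
  center containment; multiple polygons of one class are unioned.
* **CSV / JSON** — measurement tables, segmentation-metric tables and
  agreement reports, with fixed column orders and 6-decimal floats so
  diffs are meaningful.

The segmentation backend is a pluggable callable mapping an image to
:class:`~shoulderx.landmarks.RegionMasks`; the built-in default pairs each
image with a precomputed mask file by filename stem.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from shapely import contains_xy
from shapely.geometry import Polygon
from skimage import measure as _skmeasure

from .errors import FormatError, MissingPredictionError
from .landmarks import RegionMasks, largest_component
from .measures import MeasurementRecord
from .metrics import RatingsTable

#: Fixed label-map encoding (background = 0).
LABEL_ENCODING: dict[str, int] = {"acromion": 1, "glenoid": 2, "humerus": 3}
#: Polygon-file class order.
POLYGON_CLASS_ORDER: tuple[str, ...] = ("acromion", "glenoid", "humerus")

FLOAT_FORMAT = "%.6f"


# --------------------------------------------------------------------------
# label maps


def regions_to_label_map(regions: RegionMasks) -> np.ndarray:
    """Encode disjoint region masks as a uint8 label raster."""
    overlap = (
        (regions.acromion & regions.glenoid)
        | (regions.acromion & regions.humerus)
        | (regions.glenoid & regions.humerus)
    )
    if overlap.any():
        raise FormatError("regions overlap; cannot encode as a single label map")
    out = np.zeros(regions.shape, dtype=np.uint8)
    for name, mask in regions.items():
        out[mask] = LABEL_ENCODING[name]
    return out


def label_map_to_regions(label_map: np.ndarray) -> RegionMasks:
    label_map = np.asarray(label_map)
    known = np.isin(label_map, (0, *LABEL_ENCODING.values()))
    if not known.all():
        bad = np.unique(label_map[~known])
        raise FormatError(f"label map contains unknown label value(s) {bad.tolist()}")
    return RegionMasks(
        acromion=label_map == LABEL_ENCODING["acromion"],
        glenoid=label_map == LABEL_ENCODING["glenoid"],
        humerus=label_map == LABEL_ENCODING["humerus"],
    )


def write_label_map(path: str | Path, regions: RegionMasks) -> None:
    Image.fromarray(regions_to_label_map(regions), mode="L").save(Path(path))


def read_label_map(path: str | Path) -> RegionMasks:
    """Read an 8-bit label-map PNG into per-class binary masks."""
    path = Path(path)
    with Image.open(path) as img:
        if img.mode != "L":
            raise FormatError(f"{path.name}: expected single-channel 8-bit PNG, got mode {img.mode}")
        arr = np.asarray(img, dtype=np.uint8)
    return label_map_to_regions(arr)


# --------------------------------------------------------------------------
# polygon text


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(Path(path))


def read_yolo_polygons(path: str | Path, image_size: tuple[int, int]) -> RegionMasks:
    """Rasterize a polygon text file at the stated (height, width).

    Each line: ``class_id x1 y1 x2 y2 ...`` with >= 3 vertices in
    normalized [0, 1] coordinates.  Fill rule: a pixel belongs to the
    polygon iff its integer-coordinate center is strictly inside (even-odd
    rule).  Multiple polygons per class are unioned before downstream
    largest-component selection.
    """
    path = Path(path)
    h, w = image_size
    masks = {name: np.zeros((h, w), dtype=bool) for name in POLYGON_CLASS_ORDER}
    yy, xx = np.mgrid[:h, :w]
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        try:
            class_id = int(fields[0])
            coords = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: non-numeric field ({exc})") from exc
        if class_id not in range(len(POLYGON_CLASS_ORDER)):
            raise FormatError(f"{path.name}:{lineno}: unknown class id {class_id}")
        if len(coords) % 2 != 0:
            raise FormatError(f"{path.name}:{lineno}: odd coordinate count {len(coords)}")
        if len(coords) < 6:
            raise FormatError(f"{path.name}:{lineno}: polygon needs >= 3 vertices")
        if any(not 0.0 <= v <= 1.0 for v in coords):
            raise FormatError(f"{path.name}:{lineno}: coordinate outside [0, 1]")
        verts = [(coords[i] * w, coords[i + 1] * h) for i in range(0, len(coords), 2)]
        poly = Polygon(verts)
        name = POLYGON_CLASS_ORDER[class_id]
        masks[name] |= contains_xy(poly, xx.ravel(), yy.ravel()).reshape(h, w)
    return RegionMasks(**masks)


def write_yolo_polygons(path: str | Path, regions: RegionMasks) -> None:
    """Trace each region's largest component into one normalized polygon line.

    Contours are extracted at the half-level between foreground and
    background, so a write/read round trip reproduces the mask to DSC >=
    0.99 (subpixel contours vs. pixel-center fill) rather than bit-exactly.
    """
    h, w = regions.shape
    lines = []
    for class_id, name in enumerate(POLYGON_CLASS_ORDER):
        mask = largest_component(getattr(regions, name))
        if not mask.any():
            continue
        padded = np.pad(mask.astype(float), 1)
        contours = _skmeasure.find_contours(padded, 0.5)
        contour = max(contours, key=len) - 1.0  # (row, col), undo pad
        coords = []
        for r, c in contour:
            coords.append(min(max(c / w, 0.0), 1.0))
            coords.append(min(max(r / h, 0.0), 1.0))
        lines.append(" ".join([str(class_id)] + [f"{v:.6f}" for v in coords]))
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# segmentation backend contract


def validate_backend_output(result: RegionMasks, expected_shape: tuple[int, int]) -> RegionMasks:
    """Contract check for backend adapters: RegionMasks of the image's shape."""
    if not isinstance(result, RegionMasks):
        raise TypeError(f"backend must return RegionMasks, got {type(result).__name__}")
    if result.shape != tuple(expected_shape):
        raise ValueError(
            f"backend returned masks of shape {result.shape}, expected {tuple(expected_shape)}"
        )
    return result


class PrecomputedMaskLoader:
    """Default segmentation backend: pair images with mask files by stem.

    ``mask_format`` is ``"labelmap"`` (``<stem>.png`` label maps) or
    ``"yolo"`` (``<stem>.txt`` polygon files, rasterized at the image's
    size).  Duplicate stems in the mask directory are an error, not a guess.
    """

    def __init__(self, mask_dir: str | Path, mask_format: str = "labelmap"):
        if mask_format not in ("labelmap", "yolo"):
            raise ValueError(f"unknown mask format {mask_format!r}")
        self.mask_dir = Path(mask_dir)
        self.mask_format = mask_format
        suffix = ".png" if mask_format == "labelmap" else ".txt"
        self._by_stem: dict[str, Path] = {}
        for p in sorted(self.mask_dir.glob(f"*{suffix}")):
            if p.stem in self._by_stem:
                raise FormatError(f"duplicate mask stem {p.stem!r} in {self.mask_dir}")
            self._by_stem[p.stem] = p

    def __call__(self, image_path: str | Path) -> RegionMasks:
        image_path = Path(image_path)
        mask_path = self._by_stem.get(image_path.stem)
        if mask_path is None:
            raise MissingPredictionError(f"no mask file for image {image_path.name!r}")
        if self.mask_format == "labelmap":
            return read_label_map(mask_path)
        with Image.open(image_path) as img:
            h, w = img.height, img.width
        return read_yolo_polygons(mask_path, (h, w))


SegmentationBackend = Callable[[Path], RegionMasks]


# --------------------------------------------------------------------------
# tables and reports


def write_measurements_csv(path: str | Path, records: Iterable[MeasurementRecord]) -> None:
    df = pd.DataFrame([r.to_row() for r in records], columns=MeasurementRecord.CSV_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_measurements_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MeasurementRecord.CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {sorted(missing)}")
    return df


def read_ratings_csv(path: str | Path, measure_name: str = "") -> RatingsTable:
    """Read a repeated-ratings table in wide or long format.

    Wide: a ``subject`` column plus one column per repeat.  Long: columns
    ``subject``, ``repeat``, ``value``.  Both produce an n x k grid.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"subject", "repeat", "value"} <= cols:
        wide = df.pivot(index="subject", columns="repeat", values="value")
        if wide.isna().any().any():
            raise FormatError(f"{Path(path).name}: missing cells after pivoting long format")
        return RatingsTable(wide.to_numpy(), measure_name)
    if "subject" in cols and len(df.columns) >= 3:
        values = df.drop(columns=["subject"]).to_numpy(dtype=float)
        return RatingsTable(values, measure_name)
    raise FormatError(
        f"{Path(path).name}: expected wide (subject + repeat columns) or "
        "long (subject, repeat, value) ratings format"
    )


def write_json_report(path: str | Path, payload: dict) -> None:
    def _round(obj):
        if isinstance(obj, float):
            return round(obj, 6)
        if isinstance(obj, dict):
            return {k: _round(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_round(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(_round(payload), indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON study configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise FormatError(f"{path.name}: config must be a mapping")
    return loaded


def find_images(image_dir: str | Path, pattern: str = "*.png") -> list[Path]:
    paths = sorted(Path(image_dir).glob(pattern))
    stems = [p.stem for p in paths]
    dupes = {s for s in stems if stems.count(s) > 1}
    if dupes:
        raise FormatError(f"duplicate image stems {sorted(dupes)} in {image_dir}")
    return paths
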