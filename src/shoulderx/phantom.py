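"""Synthetic shoulder phantoms with known ground-truth measurements.

The generator inverts the three measurement constructions in closed form:
given target CSA, AI and LAA values it places the four landmarks

* G, I on a vertical glenoid segment of prescribed length L,
* A on the ray leaving I at exactly the CSA angle from I->G toward lateral,
  at lateral offset ``d_A = 0.7 L`` (an anatomically plausible lateral
  acromial extension; the ratio is the generator's one free parameter),
* H at lateral offset ``d_H = d_A / AI`` with its row chosen so the angle at
  V = midpoint(G, I) between V->A and V->H is exactly the LAA target,

so the forward measurements reproduce the targets to machine precision on
the continuous landmarks.  The landmarks are then rasterized as three
disjoint bone-like regions — a glenoid strip, an acromion slab with a
tapered medial end, and a humeral-head disk — whose extremal boundary
pixels land on the (rounded) landmarks, which bounds the raster pipeline's
recovery error by the 0.5-px quantization per coordinate.

Shape details (strip width, slab thickness and length, disk radius) are
seeded-random within ranges proportional to L, so phantoms vary without
moving the extremal landmarks.  Infeasible target triples (e.g. a humeral
ray turned past the lateral axis) raise instead of being clipped.

The module also carries the dataset bookkeeping used for training-style
experiments: an augmentation scheme of the four axis-aligned symmetries
(identity, x-flip, y-flip, 180-degree rotation — a 140-image set becomes
560) and a seeded train/test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .errors import InfeasibleSpecError, RenderingError
from .geometry import Point
from .landmarks import LandmarkSet, RegionMasks
from .measures import compute_ai, compute_csa, compute_laa

#: Lateral offset of the acromion landmark as a fraction of glenoid length.
ACROMION_OFFSET_FRACTION = 0.7

#: Canvas margin as a fraction of glenoid length (covers the largest random
#: shape extents: disk radius <= 0.16 L, slab thickness <= 0.13 L).
_PAD_FRACTION = 0.34
_PAD_EXTRA = 12


@dataclass(frozen=True)
class PhantomSpec:
    """Prescribed target measurements and rendering parameters."""

    csa_target: float
    ai_target: float
    laa_target: float
    glenoid_length: float = 120.0
    image_size: tuple[int, int] | None = None  # (height, width); None = auto
    seed: int = 0

    def __post_init__(self) -> None:
        if not 5 < self.csa_target < 80:
            raise InfeasibleSpecError(f"CSA target {self.csa_target} outside (5, 80) deg")
        if not 0.3 < self.ai_target < 1.6:
            raise InfeasibleSpecError(f"AI target {self.ai_target} outside (0.3, 1.6)")
        if not 20 < self.laa_target < 90:
            raise InfeasibleSpecError(f"LAA target {self.laa_target} outside (20, 90) deg")
        if self.glenoid_length < 40:
            raise InfeasibleSpecError(
                f"glenoid_length {self.glenoid_length} below the 40-px minimum"
            )


@dataclass(frozen=True)
class PhantomTruth:
    """Continuous ground-truth landmarks and the realized measurement values."""

    landmarks: LandmarkSet
    csa: float
    ai: float
    laa: float
    spec: PhantomSpec
    image_size: tuple[int, int] = field(default=(0, 0))


def solve_landmarks(spec: PhantomSpec) -> PhantomTruth:
    """Closed-form landmark placement realizing the spec's target triple.

    Raises :class:`InfeasibleSpecError` when the required humeral ray is
    not lateral-pointing or the landmarks do not fit a requested canvas
    with a 10-px margin.
    """
    L = float(spec.glenoid_length)
    d_a = ACROMION_OFFSET_FRACTION * L
    csa = math.radians(spec.csa_target)
    laa = math.radians(spec.laa_target)

    # Raw frame: G at origin, glenoid line along +y (inferior), lateral = +x.
    a_y = L - d_a / math.tan(csa)
    theta_a = math.atan2(a_y - L / 2.0, d_a)
    theta_h = theta_a + laa
    if math.cos(theta_h) <= 1e-6:
        raise InfeasibleSpecError(
            "humeral ray parallel to or past the glenoid line "
            f"(theta_H = {math.degrees(theta_h):.1f} deg); reduce LAA or CSA"
        )
    d_h = d_a / spec.ai_target
    h_y = L / 2.0 + d_h * math.tan(theta_h)

    # Integer translation so everything (landmarks + random shape extents)
    # fits the canvas; measurements are translation-invariant.
    pad = math.ceil(_PAD_FRACTION * L) + _PAD_EXTRA
    tx = pad
    ty = math.ceil(pad - min(0.0, a_y, h_y))
    lm = LandmarkSet(
        G=Point(tx, ty),
        I=Point(tx, ty + L),
        A=Point(tx + d_a, ty + a_y),
        H=Point(tx + d_h, ty + h_y),
        lateral_sign=+1,
    )
    height = math.ceil(max(lm.I.y, lm.A.y, lm.H.y)) + pad
    width = math.ceil(max(lm.A.x, lm.H.x)) + pad
    if spec.image_size is not None:
        req_h, req_w = spec.image_size
        xs = (lm.G.x, lm.A.x, lm.H.x)
        ys = (lm.G.y, lm.I.y, lm.A.y, lm.H.y)
        if (
            min(xs) < 10
            or min(ys) < 10
            or max(xs) > req_w - 11
            or max(ys) > req_h - 11
        ):
            raise InfeasibleSpecError(
                f"landmarks do not fit a {req_h}x{req_w} canvas with 10-px margin"
            )
        height, width = req_h, req_w

    truth = PhantomTruth(
        landmarks=lm,
        csa=compute_csa(lm),
        ai=compute_ai(lm),
        laa=compute_laa(lm),
        spec=spec,
        image_size=(height, width),
    )
    # Construction is exact on continuous landmarks; guard against drift.
    if (
        abs(truth.csa - spec.csa_target) > 1e-9
        or abs(truth.ai - spec.ai_target) > 1e-9
        or abs(truth.laa - spec.laa_target) > 1e-9
    ):  # pragma: no cover - defensive
        raise InfeasibleSpecError("closed-form construction failed to realize targets")
    return truth


def render_masks(truth: PhantomTruth) -> RegionMasks:
    """Rasterize phantom landmarks into three disjoint region masks.

    The glenoid strip's extremal boundary rows land on G and I, the acromion
    slab's lateral-most (tie: inferior) boundary pixel on A, and the humeral
    disk's lateral-most (tie: superior) boundary pixel on H — each within
    the 0.5-px-per-coordinate rounding of the continuous truth.
    """
    spec = truth.spec
    rng = np.random.default_rng(spec.seed)
    L = float(spec.glenoid_length)
    h, w = truth.image_size
    lm = truth.landmarks

    gx, gy0 = round(lm.G.x), round(lm.G.y)
    gy1 = round(lm.I.y)
    ax, ay = round(lm.A.x), round(lm.A.y)
    hx, hy = round(lm.H.x), round(lm.H.y)

    glenoid = np.zeros((h, w), dtype=bool)
    strip_w = int(rng.integers(4, max(5, round(0.07 * L)) + 1))
    glenoid[gy0 : gy1 + 1, gx - strip_w + 1 : gx + 1] = True

    acromion = np.zeros((h, w), dtype=bool)
    thick = int(rng.integers(max(3, round(0.07 * L)), max(4, round(0.13 * L)) + 1))
    length = int(rng.integers(max(6, round(0.22 * L)), max(7, round(0.38 * L)) + 1))
    length = min(length, ax - gx - 3)
    acromion[ay - thick : ay + 1, ax - length : ax + 1] = True
    # Tapered medial end: staircase cut of the top-medial corner; never
    # touches the lateral column or the bottom row.
    taper = int(rng.integers(0, thick // 2 + 1))
    for i in range(taper):
        acromion[ay - thick : ay - thick + (taper - i), ax - length + i] = False

    humerus = np.zeros((h, w), dtype=bool)
    radius = int(rng.integers(max(4, round(0.10 * L)), max(5, round(0.16 * L)) + 1))
    yy, xx = np.ogrid[:h, :w]
    humerus |= (xx - (hx - radius)) ** 2 + (yy - hy) ** 2 <= radius**2

    for name_a, a, name_b, b in (
        ("glenoid", glenoid, "acromion", acromion),
        ("glenoid", glenoid, "humerus", humerus),
        ("acromion", acromion, "humerus", humerus),
    ):
        if (a & b).any():
            raise RenderingError(
                f"rasterized {name_a} and {name_b} overlap; "
                "regenerate with a larger canvas or different targets"
            )
    return RegionMasks(acromion=acromion, glenoid=glenoid, humerus=humerus)


def generate_phantom(spec: PhantomSpec) -> tuple[PhantomTruth, RegionMasks]:
    """Convenience: solve landmarks and render masks in one call."""
    truth = solve_landmarks(spec)
    return truth, render_masks(truth)


def render_image(masks: RegionMasks, seed: int = 0) -> np.ndarray:
    """Synthetic radiograph-like grayscale image (uint8) for a mask set.

    A smooth illumination gradient plus mild noise, with the bone regions
    brightened and blurred to fake soft cortical edges.  Purely cosmetic —
    the measurement pipeline never reads these images.
    """
    rng = np.random.default_rng(seed)
    h, w = masks.shape
    yy, xx = np.mgrid[:h, :w]
    img = 40.0 + 30.0 * (xx / max(w - 1, 1)) + 15.0 * (yy / max(h - 1, 1))
    img += rng.normal(0.0, 3.0, size=(h, w))
    bone = (masks.acromion | masks.glenoid | masks.humerus).astype(float)
    img += 140.0 * ndimage.gaussian_filter(bone, sigma=1.2)
    return np.clip(img, 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# dataset bookkeeping: augmentation and splits


def _identity(a: np.ndarray) -> np.ndarray:
    return a.copy()


def _flip_x(a: np.ndarray) -> np.ndarray:
    return a[:, ::-1].copy()


def _flip_y(a: np.ndarray) -> np.ndarray:
    return a[::-1, :].copy()


def _rot180(a: np.ndarray) -> np.ndarray:
    return a[::-1, ::-1].copy()


TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": _identity,
    "flip_x": _flip_x,
    "flip_y": _flip_y,
    "rot180": _rot180,
}


@dataclass(frozen=True)
class AugmentationScheme:
    """An ordered set of distinct axis-aligned raster transforms."""

    transforms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.transforms:
            raise ValueError("augmentation scheme must contain at least one transform")
        if len(set(self.transforms)) != len(self.transforms):
            raise ValueError("augmentation transforms must be distinct")
        unknown = [t for t in self.transforms if t not in TRANSFORMS]
        if unknown:
            raise ValueError(f"unknown transforms {unknown}; known: {sorted(TRANSFORMS)}")


#: Four variants per image: the expansion that turns 140 items into 560.
DEFAULT_AUGMENTATION = AugmentationScheme(("identity", "flip_x", "flip_y", "rot180"))


def apply_transform(name: str, image: np.ndarray, masks: RegionMasks) -> tuple[np.ndarray, RegionMasks]:
    fn = TRANSFORMS[name]
    return fn(image), RegionMasks(
        acromion=fn(masks.acromion), glenoid=fn(masks.glenoid), humerus=fn(masks.humerus)
    )


def augment(
    items: Sequence[tuple[np.ndarray, RegionMasks]],
    scheme: AugmentationScheme = DEFAULT_AUGMENTATION,
) -> list[tuple[np.ndarray, RegionMasks]]:
    """Expand a dataset: one output per (item, transform) pair.

    Masks are transformed identically to images; every transform preserves
    foreground pixel counts (pure index permutations).
    """
    if not items:
        raise ValueError("augment requires at least one item")
    out: list[tuple[np.ndarray, RegionMasks]] = []
    for image, masks in items:
        for name in scheme.transforms:
            out.append(apply_transform(name, image, masks))
    return out


def split_dataset(ids: Sequence, n_train: int, seed: int) -> tuple[list, list]:
    """Seeded disjoint, exhaustive train/test split of a sequence of ids."""
    ids = list(ids)
    if not 0 < n_train < len(ids):
        raise ValueError(f"n_train must be in (0, {len(ids)}), got {n_train}")
    perm = np.random.default_rng(seed).permutation(len(ids))
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


def corrupt_masks(
    masks: RegionMasks, amount: int = 1, mode: str = "dilate", seed: int | None = None
) -> RegionMasks:
    """Boundary erosion/dilation to emulate imperfect segmentations.

    ``mode`` is ``dilate``, ``erode`` or ``random`` (per-region choice).
    Not calibrated to any particular segmenter's error statistics; intended
    for robustness tests.
    """
    if mode not in ("dilate", "erode", "random"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    rng = np.random.default_rng(seed)

    def one(m: np.ndarray) -> np.ndarray:
        op = mode if mode != "random" else ("dilate" if rng.random() < 0.5 else "erode")
        fn = ndimage.binary_dilation if op == "dilate" else ndimage.binary_erosion
        return fn(m, iterations=amount)

    return RegionMasks(
        acromion=one(masks.acromion), glenoid=one(masks.glenoid), humerus=one(masks.humerus)
    )


def random_feasible_spec(
    rng: np.random.Generator,
    glenoid_length: float = 120.0,
    csa_range: tuple[float, float] = (25.0, 45.0),
    ai_range: tuple[float, float] = (0.5, 1.1),
    laa_range: tuple[float, float] = (40.0, 70.0),
) -> PhantomSpec:
    """Draw a spec uniformly from a box of jointly feasible targets.

    The default box sits inside the clinically observed value ranges and is
    feasible everywhere for the closed-form construction.
    """
    return PhantomSpec(
        csa_target=float(rng.uniform(*csa_range)),
        ai_target=float(rng.uniform(*ai_range)),
        laa_target=float(rng.uniform(*laa_range)),
        glenoid_length=glenoid_length,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
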