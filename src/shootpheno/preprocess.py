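"""Image standardization before segmentation.

Coordinate convention (used across the whole package): row-major arrays,
top-left origin, half-open windows ``[row0, row1) x [col0, col1)``.

Three steps make pixel counts comparable across captures: cropping to a
standard window/size, masking out known non-plant structures (pot, support
strut, frame margins) via color-box and zone rules, and rescaling images to
a common pixel-per-millimetre ratio.  Images are resampled bilinearly,
masks with nearest neighbour so they stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

__all__ = [
    "PlantImage",
    "CropSpec",
    "ObstacleRules",
    "ColorBox",
    "crop_and_standardize",
    "exclude_obstacles",
    "normalize_scale",
]


@dataclass
class PlantImage:
    """One RGB capture of one plant at one view and day.

    ``pixels`` is an (H, W, 3) uint8 array; ``px_per_mm`` converts pixel
    lengths to physical lengths and must be positive.
    """

    pixels: np.ndarray
    view: str = "vertical"
    plant_id: str = ""
    variety: str = ""
    treatment: str = "unstressed"
    stage: str = "V3"
    day: int = 0
    px_per_mm: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("PlantImage.pixels must be (H, W, 3)")
        if px.shape[0] == 0 or px.shape[1] == 0:
            raise ValueError("PlantImage must have positive height and width")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class CropSpec:
    """Half-open crop window plus the output size it is resampled to."""

    window: tuple[int, int, int, int]  # row0, row1, col0, col1
    target_size: tuple[int, int]  # H, W

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.window
        if not (r0 < r1 and c0 < c1):
            raise ValueError("crop window must be non-empty")
        if self.target_size[0] <= 0 or self.target_size[1] <= 0:
            raise ValueError("target_size must be positive")


@dataclass(frozen=True)
class ColorBox:
    """Per-channel inclusive [min, max] level box in RGB."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def mask(self, pixels: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((pixels >= lo) & (pixels <= hi), axis=2)

    def contains_box(self, other: "ColorBox") -> bool:
        return all(a <= b for a, b in zip(self.lo, other.lo)) and all(
            a >= b for a, b in zip(self.hi, other.hi)
        )


@dataclass
class ObstacleRules:
    """Declarative exclusion rules: color boxes, fixed zones, margins.

    ``zones`` are half-open (row0, row1, col0, col1) rectangles always
    excluded; ``margin`` excludes a frame of that many pixels around the
    border.  ``foreground`` is a color box that is never excluded, whatever
    the other rules say (it guards leaf pixels against over-broad boxes).
    """

    color_boxes: list[ColorBox] = field(default_factory=list)
    zones: list[tuple[int, int, int, int]] = field(default_factory=list)
    margin: int = 0
    foreground: ColorBox | None = None

    def __post_init__(self) -> None:
        if self.foreground is not None:
            for box in self.color_boxes:
                if box.contains_box(self.foreground):
                    raise ValueError(
                        "contradictory rules: an exclusion color box fully "
                        "contains the foreground box"
                    )


def crop_and_standardize(image: PlantImage, spec: CropSpec) -> PlantImage:
    """Crop to ``spec.window`` and resample to ``spec.target_size``.

    Bilinear resampling; ``px_per_mm`` is rescaled by the geometric-mean
    resize factor so physical areas stay consistent.  Metadata is preserved.
    """
    r0, r1, c0, c1 = spec.window
    h, w = image.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(
            f"crop window {spec.window} outside image of shape {(h, w)}"
        )
    block = image.pixels[r0:r1, c0:c1]
    th, tw = spec.target_size
    if (th, tw) == block.shape[:2]:
        out = block.copy()
        factor = 1.0
    else:
        fy = th / block.shape[0]
        fx = tw / block.shape[1]
        out = resize(
            block, (th, tw), order=1, preserve_range=True, anti_aliasing=False
        )
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
        factor = float(np.sqrt(fy * fx))
    return replace(image, pixels=out, px_per_mm=image.px_per_mm * factor)


def exclude_obstacles(image: PlantImage, rules: ObstacleRules) -> np.ndarray:
    """Boolean (H, W) mask of pixels segmentation must ignore."""
    h, w = image.shape
    excl = np.zeros((h, w), dtype=bool)
    for box in rules.color_boxes:
        excl |= box.mask(image.pixels)
    for r0, r1, c0, c1 in rules.zones:
        excl[max(r0, 0) : max(r1, 0), max(c0, 0) : max(c1, 0)] = True
    if rules.margin > 0:
        m = rules.margin
        excl[:m, :] = True
        excl[-m:, :] = True
        excl[:, :m] = True
        excl[:, -m:] = True
    if rules.foreground is not None:
        excl &= ~rules.foreground.mask(image.pixels)
    return excl


def normalize_scale(image: PlantImage, target_px_per_mm: float) -> PlantImage:
    """Resample so the image has ``target_px_per_mm`` pixels per mm.

    Physical areas (px count / px_per_mm²) are conserved within resampling
    tolerance.  A no-op when the scale already matches to 1 part in 1e6.
    """
    if target_px_per_mm <= 0:
        raise ValueError("target_px_per_mm must be positive")
    if image.px_per_mm is None or image.px_per_mm <= 0:
        raise ValueError(
            "source px_per_mm is unknown; set PlantImage.px_per_mm before "
            "scale normalization"
        )
    factor = target_px_per_mm / image.px_per_mm
    if abs(factor - 1.0) < 1e-6:
        return image
    h, w = image.shape
    th = max(1, int(round(h * factor)))
    tw = max(1, int(round(w * factor)))
    out = resize(
        image.pixels, (th, tw), order=1, preserve_range=True, anti_aliasing=factor < 1
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return replace(image, pixels=out, px_per_mm=target_px_per_mm)
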