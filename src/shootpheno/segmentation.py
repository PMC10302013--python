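"""Foreground segmentation of plant shoots.

The default path is the standard canopy-segmentation recipe: merge the RGB
bands into an excess-green score (2G - R - B, rescaled to 0..255), take a
single Otsu threshold, keep the above-threshold (green-dominant) class,
zero out the obstacle-exclusion mask, clean up by morphological opening,
drop tiny components and label the remainder with 8-connectivity.  A
"literal" alternative — binarize each band separately by Otsu, then merge
the binaries — is kept behind ``band_mode`` for comparison.

The Otsu threshold is computed from the 256-bin histogram by maximizing the
between-class variance w0*w1*(mu0-mu1)^2 over all splits {<=t} vs {>t},
t in 0..254, ties broken by the smallest t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label
from skimage.morphology import disk, opening

from .preprocess import PlantImage

__all__ = [
    "BinaryMask",
    "SegmentationResult",
    "SegmentationParams",
    "split_channels",
    "merge_to_gray",
    "otsu_threshold",
    "segment",
    "jaccard",
]


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks (1.0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)

EXCESS_GREEN_WEIGHTS = (-1.0, 2.0, -1.0)


@dataclass
class BinaryMask:
    """Boolean foreground mask with its physical scale."""

    pixels: np.ndarray
    px_per_mm: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask.pixels must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SegmentationResult:
    """ROI mask plus its connected components.

    ``labels`` is an int array, 0 = background, 1..n = components;
    component i occupies ``labels == i`` and has ``component_sizes[i-1]``
    pixels.  ``largest_component_index`` is the 1-based label of the
    biggest component, or 0 when the ROI is empty.
    """

    roi: BinaryMask
    labels: np.ndarray
    component_sizes: list[int] = field(default_factory=list)
    otsu_level: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)

    @property
    def largest_component_index(self) -> int:
        if not self.component_sizes:
            return 0
        return 1 + int(np.argmax(self.component_sizes))


@dataclass(frozen=True)
class SegmentationParams:
    band_mode: str = "merged"  # "merged" (excess-green + one Otsu) | "literal"
    opening_radius: int = 1
    min_component_px: int = 25

    def __post_init__(self) -> None:
        if self.band_mode not in ("merged", "literal"):
            raise ValueError("band_mode must be 'merged' or 'literal'")
        if self.opening_radius < 0 or self.min_component_px < 0:
            raise ValueError("parameters must be >= 0")


def split_channels(image: PlantImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the R, G, B bands as separate (H, W) uint8 arrays."""
    px = image.pixels
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    return px[:, :, 0].copy(), px[:, :, 1].copy(), px[:, :, 2].copy()


def merge_to_gray(bands, weights=EXCESS_GREEN_WEIGHTS) -> np.ndarray:
    """Weighted band combination rescaled linearly to the full 0..255 range.

    With the default excess-green weights the raw score is 2G - R - B,
    which spans [-510, 510]; the affine rescale maps that span onto
    [0, 255] so mid-level 127.5 corresponds to zero excess green.  The
    result is float to avoid quantization before thresholding, and is
    strictly monotone in G for fixed R and B.
    """
    r, g, b = (np.asarray(x, dtype=float) for x in bands)
    if not (r.shape == g.shape == b.shape):
        raise ValueError("band shapes differ")
    w = np.asarray(weights, dtype=float)
    pos = w.clip(min=0).sum() * 255.0
    neg = w.clip(max=0).sum() * 255.0
    if pos + (-neg) <= 0:
        raise ValueError("weights must have positive total magnitude")
    raw = w[0] * r + w[1] * g + w[2] * b
    return (raw - neg) / (pos - neg) * 255.0


def otsu_threshold(histogram) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns t in 0..254 maximizing the between-class variance of the split
    {levels <= t} vs {levels > t}; the smallest maximizing t wins ties.
    Raises on histograms with fewer than two occupied bins (no split
    separates anything).
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.any(h < 0):
        raise ValueError("histogram counts must be >= 0")
    if np.count_nonzero(h) < 2:
        raise ValueError("degenerate histogram: fewer than 2 occupied levels")
    total = h.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(h)[:-1]  # mass of {<= t}, t = 0..254
    w1 = total - w0
    m0 = np.cumsum(h * levels)[:-1]
    mean0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mean1 = np.divide(
        h @ levels - m0, w1, out=np.zeros_like(m0), where=w1 > 0
    )
    sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) tie


def _gray_histogram(gray: np.ndarray, valid: np.ndarray) -> np.ndarray:
    levels = np.clip(np.rint(gray[valid]), 0, 255).astype(np.intp)
    return np.bincount(levels, minlength=256)[:256]


def segment(
    image: PlantImage,
    exclusion: np.ndarray | None = None,
    params: SegmentationParams | None = None,
) -> SegmentationResult:
    """Full segmentation pipeline for one preprocessed image.

    merge -> Otsu -> above-threshold mask -> exclusion zeroed ->
    morphological opening -> small-component removal -> 8-connected
    labeling.  An empty ROI (a drought-killed plant may vanish) yields a
    zero-component result with a warning, never an exception.
    """
    params = params or SegmentationParams()
    h, w = image.shape
    if exclusion is None:
        exclusion = np.zeros((h, w), dtype=bool)
    exclusion = np.asarray(exclusion, dtype=bool)
    if exclusion.shape != (h, w):
        raise ValueError("exclusion mask shape differs from image")
    valid = ~exclusion

    warnings: list[str] = []
    bands = split_channels(image)
    if params.band_mode == "merged":
        gray = merge_to_gray(bands)
        try:
            level = otsu_threshold(_gray_histogram(gray, valid))
            fg = gray > level
        except ValueError:
            level, fg = 0, np.zeros((h, w), dtype=bool)
            warnings.append("degenerate merged histogram; empty foreground")
    else:  # literal reading: per-band Otsu binaries, then merge by majority
        binaries = []
        for band, sign in zip(bands, (-1, 1, -1)):
            try:
                t = otsu_threshold(_gray_histogram(band.astype(float), valid))
            except ValueError:
                binaries.append(np.zeros((h, w), dtype=bool))
                continue
            binaries.append((band > t) if sign > 0 else (band <= t))
        merged_binary = sum(b.astype(np.uint8) for b in binaries)
        try:
            level = otsu_threshold(
                _gray_histogram(merged_binary.astype(float) * 85.0, valid)
            )
        except ValueError:
            level = 0
        fg = merged_binary * 85.0 > level

    fg &= valid
    if params.opening_radius > 0 and fg.any():
        fg = opening(fg, disk(params.opening_radius))

    labels = label(fg, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= params.min_component_px) + 1
    roi = np.isin(labels, keep)
    labels = label(roi, connectivity=2)
    component_sizes = [int(s) for s in np.bincount(labels.ravel())[1:]]
    if not component_sizes:
        warnings.append("empty ROI after filtering")
    return SegmentationResult(
        roi=BinaryMask(roi, px_per_mm=image.px_per_mm),
        labels=labels,
        component_sizes=component_sizes,
        otsu_level=int(level),
        warnings=warnings,
    )
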