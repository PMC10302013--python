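"""Color-variance traits inside the plant ROI.

Three per-image color descriptors summarize leaf-color fluctuation: the
within-ROI variance of three channels.  Two channel semantics are
supported:

* ``rgb`` — the raw R, G, B bands;
* ``lab8`` (default) — an opponent-color reading: lightness
  (black 0 .. white 255), a green–red axis (green 0 .. red 255) and a
  blue–yellow axis (blue 0 .. yellow 255), each affinely mapped to 8-bit
  levels with neutral gray near 126–128.  Drought-yellowing moves leaf
  pixels up the green–red axis, so its ROI mean and variance respond to
  stress.

Variances are population variances (divide by n): ROIs contain thousands
of pixels and the convention makes small hand-computed tests exact.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2lab

from .preprocess import PlantImage

__all__ = ["convert_channels", "channel_variance", "roi_channel_stats"]

CHANNEL_NAMES = {
    "rgb": ("red", "green", "blue"),
    "lab8": ("lightness", "green_red", "blue_yellow"),
}


def convert_channels(image: PlantImage, mode: str = "lab8"):
    """Return three (H, W) float channel images on the 0..255 level scale."""
    if mode == "rgb":
        px = image.pixels.astype(float)
        return px[:, :, 0], px[:, :, 1], px[:, :, 2]
    if mode == "lab8":
        lab = rgb2lab(image.pixels)
        light = np.clip(lab[:, :, 0] / 100.0 * 255.0, 0, 255)
        green_red = np.clip(lab[:, :, 1] + 128.0, 0, 255)
        blue_yellow = np.clip(lab[:, :, 2] + 128.0, 0, 255)
        return light, green_red, blue_yellow
    raise ValueError(f"unknown color mode {mode!r}; use 'rgb' or 'lab8'")


def channel_variance(channel: np.ndarray, roi: np.ndarray) -> float:
    """Population variance of channel levels over ROI pixels only.

    Pixels outside the ROI never contribute; an empty ROI yields NaN (a
    missing trait, not zero).
    """
    roi = np.asarray(roi, dtype=bool)
    channel = np.asarray(channel, dtype=float)
    if channel.shape != roi.shape:
        raise ValueError("channel and ROI shapes differ")
    values = channel[roi]
    if values.size == 0:
        return float("nan")
    return float(np.var(values))


def roi_channel_stats(image: PlantImage, roi: np.ndarray, mode: str = "lab8"):
    """(mean, variance) per channel over the ROI; NaNs when the ROI is empty."""
    chans = convert_channels(image, mode)
    roi = np.asarray(roi, dtype=bool)
    means, variances = [], []
    for ch in chans:
        vals = ch[roi]
        if vals.size == 0:
            means.append(float("nan"))
            variances.append(float("nan"))
        else:
            means.append(float(vals.mean()))
            variances.append(float(np.var(vals)))
    return tuple(means), tuple(variances)
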