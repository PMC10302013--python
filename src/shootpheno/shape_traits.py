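"""The 13 image-based shoot traits.

Five "area" traits (projected area, object sum area, caliper length,
convex hull area, min-area-rectangle area), five "boundary" traits
(circumference, convex hull circumference, min enclosing circle diameter,
roundness, boundary point roundness) and three color-variance traits.

Geometry runs over pixel centers: pixel (row, col) is the point
(x=col, y=row), so a single pixel has caliper length 0 and the hull of a
10x10 block is a square of side 9.  By default all retained components are
pooled into one "projected object"; a per-largest-component mode exists
because the original trait table is ambiguous about multi-object images.

Undefined traits (empty ROI, fewer than two points for a caliper) are NaN,
never zero — zeros would corrupt downstream rank statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from . import geometry
from .color_traits import roi_channel_stats
from .preprocess import PlantImage
from .segmentation import BinaryMask, SegmentationResult

__all__ = [
    "TraitRecord",
    "TRAIT_NAMES",
    "mask_points",
    "boundary_points",
    "trace_perimeter",
    "rasterized_hull_count",
    "extract_traits",
]

TRAIT_NAMES = (
    "area",
    "object_sum_area",
    "caliper_length",
    "convex_hull_area",
    "min_area_rectangle_area",
    "circumference",
    "convex_hull_circumference",
    "min_enclosing_circle_diameter",
    "roundness",
    "boundary_point_roundness",
    "mean_color_red_variance",
    "mean_color_green_variance",
    "mean_color_blue_variance",
)

AREA_TRAITS = TRAIT_NAMES[:5]
BOUNDARY_TRAITS = TRAIT_NAMES[5:10]
COLOR_TRAITS = TRAIT_NAMES[10:]


@dataclass
class TraitRecord:
    """One image's identifiers plus the 13 trait values (px units)."""

    plant_id: str = ""
    variety: str = ""
    treatment: str = ""
    stage: str = ""
    day: int = 0
    view: str = ""
    area: float = math.nan
    object_sum_area: float = math.nan
    caliper_length: float = math.nan
    convex_hull_area: float = math.nan
    min_area_rectangle_area: float = math.nan
    circumference: float = math.nan
    convex_hull_circumference: float = math.nan
    min_enclosing_circle_diameter: float = math.nan
    roundness: float = math.nan
    boundary_point_roundness: float = math.nan
    mean_color_red_variance: float = math.nan
    mean_color_green_variance: float = math.nan
    mean_color_blue_variance: float = math.nan
    color_mode: str = "lab8"

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def trait_values(self) -> dict:
        return {name: getattr(self, name) for name in TRAIT_NAMES}


def mask_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixel centers as (n, 2) points (x=col, y=row)."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    return np.stack([cols, rows], axis=1).astype(float)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Centers of ROI pixels with >=1 non-ROI 4-neighbor (border = outside)."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return mask_points(m & ~interior)


# Moore neighborhood in clockwise order starting from west (row, col offsets)
_MOORE = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1))
_STEP_LEN = tuple(math.hypot(dr, dc) for dr, dc in _MOORE)


def _trace_component(mask: np.ndarray, start: tuple[int, int]) -> float:
    """Length of the outer Moore-neighbor boundary walk of one component.

    Steps between consecutive boundary pixels count 1 (axial) or sqrt(2)
    (diagonal); the walk stops when it re-enters the start pixel from the
    same direction it first left it (Jacob's criterion).  An isolated
    pixel has length 0.
    """
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    def next_on_boundary(r: int, c: int, back: int):
        # scan clockwise from the backtrack direction
        for k in range(1, 9):
            d = (back + k) % 8
            dr, dc = _MOORE[d]
            if fg(r + dr, c + dc):
                return (r + dr, c + dc), d
        return None, None

    start_next, start_dir = next_on_boundary(*start, 0)
    if start_next is None:  # isolated pixel
        return 0.0
    length = _STEP_LEN[start_dir]
    cur, came = start_next, start_dir
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        back = (came + 4) % 8  # scan resumes just past the backtrack pixel
        nxt, d = next_on_boundary(cur[0], cur[1], back)
        if cur == start and nxt == start_next and d == start_dir:
            break
        length += _STEP_LEN[d]
        cur, came = nxt, d
    return length


def trace_perimeter(labels: np.ndarray) -> float:
    """Summed Moore-trace contour length over all labeled components."""
    labels = np.asarray(labels)
    total = 0.0
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        rows, cols = np.nonzero(comp)
        if rows.size == 0:
            continue
        start = (int(rows[0]), int(cols[0]))  # raster-order first pixel
        total += _trace_component(comp, start)
    return total


def rasterized_hull_count(mask: np.ndarray, hull: np.ndarray) -> int:
    """Pixels whose centers lie inside/on the convex hull polygon."""
    m = np.asarray(mask, dtype=bool)
    if hull.shape[0] < 3:
        return int(m.sum())
    ys, xs = np.nonzero(np.ones_like(m))
    # restrict to the hull bounding box for speed
    x0, x1 = hull[:, 0].min(), hull[:, 0].max()
    y0, y1 = hull[:, 1].min(), hull[:, 1].max()
    sel = (xs >= x0) & (xs <= x1) & (ys >= y0) & (ys <= y1)
    xs, ys = xs[sel].astype(float), ys[sel].astype(float)
    inside = np.ones(xs.shape, dtype=bool)
    k = hull.shape[0]
    for i in range(k):
        ax, ay = hull[i]
        bx, by = hull[(i + 1) % k]
        cross = (bx - ax) * (ys - ay) - (by - ay) * (xs - ax)
        inside &= cross >= -1e-9  # CCW hull: inside is the left side
    return int(inside.sum())


def _mec(points: np.ndarray, seed: int) -> geometry.Circle:
    return geometry.min_enclosing_circle(points, seed=seed)


def extract_traits(
    result: SegmentationResult,
    image: PlantImage | None = None,
    *,
    object_mode: str = "union",
    circumference_mode: str = "perimeter",
    color_mode: str = "lab8",
    mec_seed: int = 0,
) -> TraitRecord:
    """Compute the 13 traits for one segmented image.

    ``object_mode`` "union" pools all retained components into the
    projected object (default); "largest" restricts the area trait and the
    geometric traits to the biggest component while ``object_sum_area``
    always sums every component.  ``circumference_mode`` "perimeter" uses
    traced contour lengths; "literal" uses pi * (min enclosing circle
    diameter), the trait table's literal wording.
    """
    if object_mode not in ("union", "largest"):
        raise ValueError("object_mode must be 'union' or 'largest'")
    if circumference_mode not in ("perimeter", "literal"):
        raise ValueError("circumference_mode must be 'perimeter' or 'literal'")

    rec = TraitRecord(color_mode=color_mode)
    if image is not None:
        rec.plant_id = image.plant_id
        rec.variety = image.variety
        rec.treatment = image.treatment
        rec.stage = image.stage
        rec.day = image.day
        rec.view = image.view

    roi = result.roi.pixels
    rec.object_sum_area = float(sum(result.component_sizes))
    if object_mode == "largest" and result.n_components > 0:
        obj = result.labels == result.largest_component_index
        obj_labels = (obj).astype(int)
    else:
        obj = roi
        obj_labels = result.labels
    rec.area = float(obj.sum())
    if rec.area == 0:
        rec.object_sum_area = 0.0
        return rec

    pts = mask_points(obj)
    hull = geometry.convex_hull(pts)
    rec.convex_hull_area = float(rasterized_hull_count(obj, hull))
    _, rect_area = geometry.min_area_rectangle(pts)
    rec.min_area_rectangle_area = float(rect_area)
    mec = _mec(pts, mec_seed)
    rec.min_enclosing_circle_diameter = float(mec.diameter)
    if pts.shape[0] >= 2:
        rec.caliper_length = geometry.caliper_length(pts)

    if circumference_mode == "perimeter":
        rec.circumference = trace_perimeter(obj_labels)
        rec.convex_hull_circumference = geometry.polygon_perimeter(hull)
    else:
        rec.circumference = math.pi * mec.diameter
        # the hull and the object share their minimum enclosing circle
        rec.convex_hull_circumference = math.pi * mec.diameter

    bpts = boundary_points(obj)
    if rec.caliper_length and rec.caliper_length > 0:
        rec.roundness = 4.0 * rec.area / (math.pi * rec.caliper_length ** 2)
        rec.boundary_point_roundness = bpts.shape[0] / (
            math.pi * (rec.caliper_length / 2.0) ** 2
        )

    if image is not None:
        _, variances = roi_channel_stats(image, obj, mode=color_mode)
        (
            rec.mean_color_red_variance,
            rec.mean_color_green_variance,
            rec.mean_color_blue_variance,
        ) = variances
    return rec


def hull_polygon_area(mask_or_points) -> float:
    """Shoelace area of the convex hull (used by containment checks)."""
    pts = (
        mask_points(mask_or_points)
        if np.asarray(mask_or_points).dtype == bool
        else np.asarray(mask_or_points, dtype=float)
    )
    return geometry.polygon_area(geometry.convex_hull(pts))
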