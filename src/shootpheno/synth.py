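"""Synthetic drought-trial generator with pixel-level ground truth.

Emulates a greenhouse drought screen on potted soybean-like plants: a panel
of varieties grown in randomized unstressed / drought-treated plots, imaged
from two angles on a fixed day grid around a 14-day water-deficit treatment
followed by a 14-day recovery.  Every rendered image comes with the exact
foreground (leaf) mask and the latent plant state that produced it, so the
whole downstream pipeline — segmentation, trait extraction, screening
statistics, embeddings — can be validated against known truth.

The biology is deliberately minimal but mechanistically shaped:

* projected shoot area follows per-variety exponential growth
  ``A(d) = A0 * (1 + g)**(d - d0)``; drought multiplies area by
  ``(1 - area_shrink_per_day)`` per treatment day, recovery restores growth
  at an elevated rate but does not erase the accumulated deficit;
* leaf color drifts from green toward yellow/red along the green–red
  opponent axis at ``yellowing_per_day`` levels per treatment day and
  relaxes back during recovery;
* plant height and node counts share the plant's vigor factor with area
  (giving medium-to-strong positive correlations by construction) and are
  frozen while the plant is under treatment.

Plants are drawn as unions of 3–9 elliptical leaf lobes (non-convex
silhouettes that exercise hull/caliper code), over background clutter: a
pot, a near-white support strut and soil-toned noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import PlantImage

__all__ = [
    "TrialConfig",
    "VarietyParams",
    "StressModel",
    "PlantState",
    "TrialDataset",
    "RenderError",
    "default_varieties",
    "simulate_growth",
    "render_plant",
    "generate_trial",
]

BACKGROUND_RGB = (152, 138, 130)  # soil-toned gray
POT_RGB = (110, 82, 60)  # gray-brown
STRUT_RGB = (236, 234, 228)  # near-white support bar


class RenderError(RuntimeError):
    """Raised when a plant cannot be drawn inside the configured canvas."""


@dataclass(frozen=True)
class StressModel:
    """Drought treatment and recovery dynamics.

    ``area_shrink_per_day``: daily fractional loss of projected area while
    soil moisture is withheld (day 0 .. treatment_days).
    ``yellowing_per_day``: daily shift of mean leaf color along the
    green->red axis, in 8-bit levels.
    ``recovery_rate``: extra daily growth fraction during re-watering,
    on top of the variety growth rate.
    """

    area_shrink_per_day: float = 0.05
    yellowing_per_day: float = 2.5
    recovery_rate: float = 0.02
    treatment_days: int = 14
    recovery_days: int = 14

    def __post_init__(self) -> None:
        if not 0.0 <= self.area_shrink_per_day <= 1.0:
            raise ValueError("area_shrink_per_day must be in [0, 1]")
        if not 0.0 <= self.recovery_rate <= 1.0:
            raise ValueError("recovery_rate must be in [0, 1]")
        if self.treatment_days < 0 or self.recovery_days < 0:
            raise ValueError("day counts must be >= 0")


@dataclass(frozen=True)
class VarietyParams:
    """Per-variety baseline growth and appearance parameters."""

    base_area_mm2: float = 1500.0
    growth_rate: float = 0.04  # fraction/day
    leaf_count_mean: float = 6.0
    green_hue: float = 170.0  # green-channel level of healthy leaves
    height_rate: float = 8.0  # mm/day

    def __post_init__(self) -> None:
        if min(self.base_area_mm2, self.growth_rate, self.leaf_count_mean,
               self.height_rate) <= 0:
            raise ValueError("variety parameters must be positive")
        if not 0 <= self.green_hue <= 255:
            raise ValueError("green_hue must be an 8-bit level")


@dataclass(frozen=True)
class TrialConfig:
    """Trial design: panel size, plot layout, day grid, imaging geometry."""

    n_varieties: int = 28
    plots_unstressed: int = 2
    plots_treated: int = 5
    n_individuals: int = 180
    stage: str = "V3"
    days: tuple[int, ...] = (-7, 0, 7, 14, 21, 28)
    views: tuple[str, ...] = ("vertical", "horizontal")
    image_size: tuple[int, int] = (256, 256)
    px_per_mm: float = 0.8
    area_noise: float = 0.08  # lognormal sigma per observation
    vigor_noise: float = 0.12  # lognormal sigma per plant
    color_noise: float = 8.0  # channel-level sigma per lobe
    drop_pre_treatment: bool = False  # emulate a missing day -7 timepoint
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_varieties, self.plots_unstressed + self.plots_treated,
               self.n_individuals) <= 0:
            raise ValueError("counts must be positive")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if self.stage not in {"V2", "V3", "V4"}:
            raise ValueError("stage must be one of V2, V3, V4")

    @property
    def n_plots(self) -> int:
        return self.plots_unstressed + self.plots_treated


@dataclass(frozen=True)
class PlantState:
    """Latent truth for one plant on one day."""

    day: int
    true_area_mm2: float
    true_height_mm: float
    node_count_main: int
    node_count_total: int
    mean_leaf_color: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.true_area_mm2 < 0 or self.true_height_mm < 0:
            raise ValueError("area and height must be >= 0")
        if self.node_count_total < self.node_count_main:
            raise ValueError("node_count_total must be >= node_count_main")


@dataclass
class TrialDataset:
    """All artifacts of one simulated trial.

    ``images`` maps (plant_id, day, view) to PlantImage, ``truth`` to
    (PlantState, boolean leaf mask); ``manifest`` has one row per image and
    ``hand_measurements`` one row per (plant, day).
    """

    images: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)
    hand_measurements: pd.DataFrame = field(default_factory=pd.DataFrame)
    config: TrialConfig | None = None


def default_varieties(n: int, seed: int = 0) -> list[VarietyParams]:
    """Sample a panel of ``n`` variety parameter sets.

    Baseline area and height rate share a common size factor, so
    image-based area and hand-measured height correlate across the panel
    as well as within plants.
    """
    rng = np.random.default_rng([seed, 250])
    out = []
    for _ in range(n):
        size = rng.lognormal(0.0, 0.20)
        out.append(
            VarietyParams(
                base_area_mm2=1500.0 * size,
                growth_rate=float(rng.uniform(0.028, 0.045)),
                leaf_count_mean=float(rng.uniform(4.0, 8.0)),
                green_hue=float(rng.uniform(150.0, 190.0)),
                height_rate=float(8.0 * size ** 0.7 * rng.lognormal(0.0, 0.08)),
            )
        )
    return out


def _rng_of(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _expected_area(variety: VarietyParams, stress: StressModel,
                   treated: bool, day: float, d0: float) -> float:
    """Baseline exponential growth, modulated by treatment.

    Drought multiplies each treatment day's growth factor by
    (1 - area_shrink_per_day); re-watering adds (1 + recovery_rate) per
    recovery day.  A zero-shrink stress model therefore leaves treated
    plants exactly on the unstressed trajectory.
    """
    g = variety.growth_rate
    area = variety.base_area_mm2 * (1.0 + g) ** (day - d0)
    if treated and day > 0 and stress.area_shrink_per_day > 0:
        t_end = stress.treatment_days
        area *= (1.0 - stress.area_shrink_per_day) ** min(day, t_end)
        # compensatory regrowth only follows an actual deficit
        area *= (1.0 + stress.recovery_rate) ** max(0.0, day - t_end)
    return area


def _stress_active(stress: StressModel) -> bool:
    return stress.area_shrink_per_day > 0 or stress.yellowing_per_day > 0


def _growth_days(stress: StressModel, treated: bool, day: float, d0: float) -> float:
    """Days of effective height/node growth (paused under active drought)."""
    if not (treated and _stress_active(stress)) or day <= 0:
        return day - d0
    return (0.0 - d0) + max(0.0, day - stress.treatment_days)


def _leaf_color(variety: VarietyParams, stress: StressModel,
                treated: bool, day: float) -> tuple[float, float, float]:
    r, g, b = 70.0, variety.green_hue, 60.0
    if treated and day > 0:
        t_end = stress.treatment_days
        shift = stress.yellowing_per_day * min(day, t_end)
        if day > t_end:  # recovery relaxes the shift at half speed
            shift = max(0.0, shift - 0.5 * stress.yellowing_per_day * (day - t_end))
        r += shift
        g -= shift
    clip = lambda v: float(np.clip(v, 0.0, 255.0))
    return (clip(r), clip(g), clip(b))


def simulate_growth(
    variety: VarietyParams,
    stress: StressModel,
    treated: bool,
    day: float,
    rng_state=0,
    *,
    day_range: tuple[float, float] | None = None,
    area_noise: float = 0.08,
    vigor: float = 1.0,
) -> PlantState:
    """Latent plant state on ``day`` (0 = treatment start).

    With ``area_noise=0`` and ``vigor=1`` the returned area is the exact
    closed-form expectation; otherwise a multiplicative lognormal
    observation factor is applied.  ``day_range`` defaults to
    ``(-7, treatment_days + recovery_days)``.
    """
    if day_range is None:
        day_range = (-7.0, float(stress.treatment_days + stress.recovery_days))
    d0, d1 = day_range
    if not d0 <= day <= d1:
        raise ValueError(f"day {day} outside configured range [{d0}, {d1}]")
    rng = _rng_of(rng_state)

    area = _expected_area(variety, stress, treated, day, d0) * vigor
    if area_noise > 0:
        area *= math.exp(area_noise * rng.standard_normal())

    eff = _growth_days(stress, treated, day, d0)
    height = (30.0 + variety.height_rate * eff) * vigor ** 0.5
    if area_noise > 0:
        height *= math.exp(0.5 * area_noise * rng.standard_normal())

    main_mean = 2.0 + 0.25 * eff
    main = 1 + int(rng.poisson(main_mean))
    total = main + int(rng.poisson(0.15 * main_mean * 2.0))
    return PlantState(
        day=int(day),
        true_area_mm2=float(area),
        true_height_mm=float(height),
        node_count_main=main,
        node_count_total=total,
        mean_leaf_color=_leaf_color(variety, stress, treated, day),
    )


def _rasterize_lobes(shape, cy, cx, offsets, axes, angles, scale):
    """Union mask of ellipses placed at center + scale*offset, axes scaled."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for (oy, ox), (a, b), th in zip(offsets, axes, angles):
        ecy, ecx = cy + scale * oy, cx + scale * ox
        ca, sa = math.cos(th), math.sin(th)
        u = (xx - ecx) * ca + (yy - ecy) * sa
        v = -(xx - ecx) * sa + (yy - ecy) * ca
        sa_, sb_ = scale * a, scale * b
        mask |= (u / sa_) ** 2 + (v / sb_) ** 2 <= 1.0
    return mask


def render_plant(
    state: PlantState,
    view: str,
    config: TrialConfig,
    rng_state=0,
    *,
    plant_id: str = "",
    color_noise: float | None = None,
) -> tuple[PlantImage, np.ndarray]:
    """Draw one plant capture; returns ``(image, truth_leaf_mask)``.

    The silhouette is a union of 3–9 elliptical lobes whose overall scale
    is calibrated against the rasterized union so the truth-mask pixel
    count matches ``state.true_area_mm2 * px_per_mm**2`` closely.  Clutter
    (pot, near-white support strut) is drawn behind the plant; the truth
    mask marks exactly the leaf pixels.
    """
    if view not in ("vertical", "horizontal"):
        raise ValueError(f"unknown view {view!r}")
    rng = _rng_of(rng_state)
    h, w = config.image_size
    noise = config.color_noise if color_noise is None else color_noise

    img = np.empty((h, w, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    img += rng.normal(0.0, 3.0, size=img.shape)

    # clutter behind the plant
    if view == "horizontal":
        pot_h = h // 5
        img[h - pot_h :, w // 6 : w - w // 6] = POT_RGB
        cy, cx = (h - pot_h) * 0.45, w * 0.5
        img[:, int(cx) - 1 : int(cx) + 2] = STRUT_RGB  # vertical support bar
    else:
        cy, cx = h * 0.5, w * 0.5
        rr = np.hypot(*np.mgrid[0:h, 0:w] - np.array([[[cy]], [[cx]]]))
        pot_r = 0.47 * min(h, w)
        img[(rr > pot_r * 0.90) & (rr <= pot_r)] = POT_RGB
        img[int(cy) - 1 : int(cy) + 2, :] = STRUT_RGB  # strut crossing the pot

    target_px = state.true_area_mm2 * config.px_per_mm ** 2
    mask = np.zeros((h, w), dtype=bool)
    if target_px >= 1.0:
        n_lobes = int(np.clip(rng.poisson(5) + 3, 3, 9))
        ang = rng.uniform(0, 2 * math.pi, size=n_lobes)
        rad = rng.uniform(0.35, 0.75, size=n_lobes)
        offsets = np.stack([np.sin(ang) * rad, np.cos(ang) * rad], axis=1)
        elong = rng.uniform(1.2, 2.2, size=n_lobes)
        base = rng.uniform(0.45, 0.75, size=n_lobes)
        axes = np.stack([base * elong, base], axis=1)
        angles = rng.uniform(0, math.pi, size=n_lobes)

        # calibrate the layout scale so the rasterized union hits target_px
        limit = min(cy, cx, h - cy, w - cx) - 2.0
        extent_factor = float(np.hypot(*np.abs(offsets).T).max() + axes.max())
        # first guess: disk-equivalent radius, but never beyond the canvas —
        # the first rasterization corrects it toward the target area
        scale = min(math.sqrt(target_px / math.pi), 0.8 * limit / extent_factor)
        for _ in range(4):
            if scale * extent_factor > limit:
                raise RenderError(
                    f"plant {plant_id or '<unnamed>'} (area "
                    f"{state.true_area_mm2:.0f} mm^2) does not fit the "
                    f"{h}x{w} canvas at {config.px_per_mm} px/mm"
                )
            mask = _rasterize_lobes((h, w), cy, cx, offsets, axes, angles, scale)
            count = int(mask.sum())
            if count == 0:
                scale *= 1.5
                continue
            ratio = target_px / count
            if abs(ratio - 1.0) < 0.01:
                break
            scale *= math.sqrt(ratio)

        # paint lobes far-to-near with per-lobe color jitter
        base_color = np.asarray(state.mean_leaf_color)
        for (oy, ox), (a, b), th in zip(offsets, axes, angles):
            lm = _rasterize_lobes((h, w), cy, cx, [(oy, ox)], [(a, b)], [th], scale)
            col = base_color + rng.normal(0.0, noise, size=3)
            img[lm] = col
        if noise > 0:
            img[mask] += rng.normal(0.0, noise * 0.4, size=(int(mask.sum()), 3))

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = PlantImage(
        pixels=pixels,
        view=view,
        plant_id=plant_id,
        day=state.day,
        px_per_mm=config.px_per_mm,
    )
    return image, mask


def _plant_roster(config: TrialConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign plants to randomized plots; trims the final unstressed plot
    when n_individuals < n_plots * n_varieties (spatial-limit emulation)."""
    treatments = ["unstressed"] * config.plots_unstressed + [
        "drought"
    ] * config.plots_treated
    order = rng.permutation(config.n_plots)
    plot_treatment = {f"P{p + 1}": treatments[k] for p, k in zip(range(config.n_plots), order)}

    rows = []
    for plot_i in range(config.n_plots):
        plot = f"P{plot_i + 1}"
        for var_i in range(config.n_varieties):
            rows.append(
                {
                    "plot": plot,
                    "treatment": plot_treatment[plot],
                    "variety": f"VAR{var_i + 1:02d}",
                    "variety_index": var_i,
                }
            )
    roster = pd.DataFrame(rows)
    excess = len(roster) - config.n_individuals
    if excess > 0:
        unstressed_plots = [p for p, t in plot_treatment.items() if t == "unstressed"]
        if not unstressed_plots:
            unstressed_plots = list(plot_treatment)
        last = unstressed_plots[-1]
        drop_idx = roster.index[roster["plot"] == last][-excess:]
        if len(drop_idx) < excess:
            raise ValueError(
                "n_individuals inconsistent with plot layout: cannot trim "
                f"{excess} plants from plot {last}"
            )
        roster = roster.drop(drop_idx)
    elif excess < 0:
        raise ValueError(
            "n_individuals exceeds n_plots * n_varieties; enlarge the panel"
        )
    roster = roster.reset_index(drop=True)
    roster["plant_id"] = [f"PL{i + 1:03d}" for i in range(len(roster))]
    return roster


def generate_trial(
    config: TrialConfig,
    varieties: list[VarietyParams] | None = None,
    stress: StressModel | None = None,
    out_dir=None,
    render: bool = True,
) -> TrialDataset:
    """Simulate a full longitudinal trial.

    Returns images for every (plant, day, view) triple, the truth mask and
    latent state per image, a manifest table, and a hand-measurement table
    (height, main/total node counts) per (plant, day).  The entire dataset
    is a pure function of (config, varieties, stress, config.seed).  With
    ``out_dir`` set, images and masks are written as PNG and the dataset
    carries file paths instead of in-memory pixel arrays.  ``render=False``
    skips drawing entirely (manifest, states and hand measurements only) —
    useful for statistics that operate on latent traits at scale.
    """
    stress = stress or StressModel()
    if varieties is None:
        varieties = default_varieties(config.n_varieties, config.seed)
    if len(varieties) != config.n_varieties:
        raise ValueError(
            f"got {len(varieties)} variety parameter sets for "
            f"n_varieties={config.n_varieties}"
        )
    root = np.random.default_rng(config.seed)
    roster = _plant_roster(config, root)
    # growth is anchored a week before treatment start even when the day
    # grid samples later timepoints only
    day_range = (min(float(min(config.days)), -7.0), float(max(config.days)))

    days = list(config.days)
    if config.drop_pre_treatment:
        days = [d for d in days if d >= 0]

    if out_dir is not None:
        import imageio.v3 as iio
        from pathlib import Path

        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    ds = TrialDataset(config=config)
    manifest_rows = []
    hand_rows = []
    for row in roster.itertuples():
        variety = varieties[row.variety_index]
        treated = row.treatment == "drought"
        p_idx = int(row.Index)
        vigor = math.exp(
            config.vigor_noise
            * np.random.default_rng([config.seed, 1, p_idx]).standard_normal()
        )
        for d_idx, day in enumerate(days):
            state = simulate_growth(
                variety,
                stress,
                treated,
                day,
                np.random.default_rng([config.seed, 2, p_idx, d_idx]),
                day_range=day_range,
                area_noise=config.area_noise,
                vigor=vigor,
            )
            hand_rows.append(
                {
                    "plant_id": row.plant_id,
                    "variety": row.variety,
                    "plot": row.plot,
                    "treatment": row.treatment,
                    "stage": config.stage,
                    "day": day,
                    "height_mm": state.true_height_mm,
                    "nodes_main": state.node_count_main,
                    "nodes_total": state.node_count_total,
                }
            )
            for v_idx, view in enumerate(config.views):
                key = (row.plant_id, day, view)
                if render:
                    image, mask = render_plant(
                        state,
                        view,
                        config,
                        np.random.default_rng([config.seed, 3, p_idx, d_idx, v_idx]),
                        plant_id=row.plant_id,
                    )
                    image.variety = row.variety
                    image.treatment = row.treatment
                    image.stage = config.stage
                else:
                    image, mask = None, None
                rec = {
                    "plant_id": row.plant_id,
                    "variety": row.variety,
                    "plot": row.plot,
                    "treatment": row.treatment,
                    "stage": config.stage,
                    "day": day,
                    "view": view,
                    "true_area_mm2": state.true_area_mm2,
                    "image_path": "",
                }
                if render and out_dir is not None:
                    name = f"{row.plant_id}_d{day:+03d}_{view}"
                    ipath = out_dir / "images" / f"{name}.png"
                    mpath = out_dir / "masks" / f"{name}.png"
                    iio.imwrite(ipath, image.pixels)
                    iio.imwrite(mpath, (mask * 255).astype(np.uint8))
                    rec["image_path"] = str(ipath)
                    rec["mask_path"] = str(mpath)
                elif render:
                    ds.images[key] = image
                ds.truth[key] = (
                    state,
                    mask if (render and out_dir is None) else None,
                )
                manifest_rows.append(rec)
    ds.manifest = pd.DataFrame(manifest_rows)
    ds.hand_measurements = pd.DataFrame(hand_rows)
    if out_dir is not None:
        ds.manifest.to_csv(out_dir / "manifest.csv", index=False)
        ds.hand_measurements.to_csv(out_dir / "hand_measurements.csv", index=False)
    return ds
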