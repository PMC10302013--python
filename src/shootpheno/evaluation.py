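"""Self-validation suites run against brute-force oracles and simulations.

Each function recomputes one family of checks from scratch — random point
sets against combinatorial geometry oracles, Otsu against exhaustive
search, segmentation against generator truth masks, rank tests against
permutation references, screening power and embedding separation on
simulated trials — and returns a small dict of summary numbers.  The test
suite asserts on these numbers; the reporting script dumps them as JSON.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import ConvexHull as SciPyHull

from . import geometry
from .embedding import build_feature_matrix, cluster_separation, pca, tsne, \
    perplexity_calibration
from .segmentation import SegmentationParams, jaccard, otsu_threshold, segment
from .shape_traits import (
    boundary_points,
    extract_traits,
    hull_polygon_area,
    mask_points,
    rasterized_hull_count,
    trace_perimeter,
)
from .stats import build_screening_tables, kruskal_wallis, to_long_table
from .shape_traits import TRAIT_NAMES
from .synth import StressModel, TrialConfig, generate_trial
from .pipeline import extract_trial_traits

__all__ = [
    "geometry_oracle_suite",
    "analytic_shape_suite",
    "otsu_equivalence",
    "trial_invariants_and_jaccard",
    "kruskal_wallis_checks",
    "screening_power_day14",
    "tsne_separation_suite",
    "tsne_calibration_check",
]


# ---------------------------------------------------------------- oracles


def brute_force_caliper(pts: np.ndarray) -> float:
    """O(n^2) max pairwise distance."""
    d2 = np.square(pts[:, None, :] - pts[None, :, :]).sum(-1)
    return float(np.sqrt(d2.max()))


def brute_force_hull_vertices(pts: np.ndarray) -> np.ndarray:
    """O(n^3) hull-edge test: a directed pair (i, j) is a hull edge iff
    every other point lies on its left; returns the unique edge endpoints."""
    n = pts.shape[0]
    verts = set()
    for i in range(n):
        for j in range(n):
            if i == j or (pts[i] == pts[j]).all():
                continue
            d = pts - pts[i]
            cross = (pts[j, 0] - pts[i, 0]) * d[:, 1] - (
                pts[j, 1] - pts[i, 1]
            ) * d[:, 0]
            on_edge = np.abs(cross) < 1e-9
            if np.all(cross >= -1e-9) and on_edge.sum() >= 2:
                verts.add(i)
                verts.add(j)
    return pts[sorted(verts)]


def angle_sweep_rectangle_area(pts: np.ndarray, step_deg: float = 0.1) -> float:
    """Min enclosing-rectangle area over a dense grid of orientations."""
    thetas = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    ca, sa = np.cos(thetas), np.sin(thetas)
    pu = pts[:, 0][:, None] * ca + pts[:, 1][:, None] * sa
    pn = -pts[:, 0][:, None] * sa + pts[:, 1][:, None] * ca
    w = pu.max(0) - pu.min(0)
    h = pn.max(0) - pn.min(0)
    return float((w * h).min())


def brute_force_mec_radius(pts: np.ndarray) -> float:
    """Smallest enclosing radius over all pair- and triple-defined circles."""
    n = pts.shape[0]
    best = math.inf
    tol = 1e-9
    for i in range(n):
        for j in range(i + 1, n):
            c = geometry._circle_from([tuple(pts[i]), tuple(pts[j])])
            if c.radius < best and _covers(c, pts, tol):
                best = c.radius
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                c = geometry._circle_from(
                    [tuple(pts[i]), tuple(pts[j]), tuple(pts[k])]
                )
                if c.radius < best and _covers(c, pts, tol):
                    best = c.radius
    return best


def _covers(c: geometry.Circle, pts: np.ndarray, tol: float) -> bool:
    d = np.hypot(pts[:, 0] - c.cx, pts[:, 1] - c.cy)
    return bool(np.all(d <= c.radius + tol))


def permutation_kw_p(groups, n_perm: int, rng, use_own: bool = True):
    """Monte-Carlo permutation p of the KW statistic.

    ``use_own=True`` evaluates the package's H; ``use_own=False`` uses an
    independent route — the rank variance decomposition
    H = (N-1) * SS_between / SS_total, algebraically distinct from the
    rank-sum formula but equal for tie-corrected H.  With the same ``rng``
    seed the two paths see identical permutations (common random numbers),
    so their p-values differ only where the H implementations disagree.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n_total = pooled.size

    def h_own(values):
        return kruskal_wallis(
            np.split(values, np.cumsum(sizes)[:-1])
        )[0]

    def h_oracle(values):
        r = sps.rankdata(values)
        sst = ((r - r.mean()) ** 2).sum()
        if sst == 0:
            return 0.0
        ssb, start = 0.0, 0
        for s in sizes:
            ssb += s * (r[start : start + s].mean() - r.mean()) ** 2
            start += s
        return (n_total - 1) * ssb / sst

    h_fun = h_own if use_own else h_oracle
    h_obs = h_fun(pooled)
    count = 0
    for _ in range(n_perm):
        if h_fun(rng.permutation(pooled)) >= h_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------- suites


def geometry_oracle_suite(seed: int = 0, n_sets: int = 1000) -> dict:
    """Random point sets vs brute-force oracles for all four primitives.

    Sizes are mostly small (where the O(n^3)/O(n^4) oracles are exact and
    cheap) with a tail up to 500 points checked against scipy's
    independent hull and the angle-sweep/caliper oracles.
    """
    rng = np.random.default_rng(seed)
    errs = {"caliper": 0.0, "hull_area": 0.0, "rect": 0.0, "mec": 0.0}
    hull_vertex_mismatch = 0
    max_n = 0
    for idx in range(n_sets):
        if idx % 20 == 19:
            n = int(rng.integers(61, 501))
        else:
            n = int(rng.integers(3, 61))
        max_n = max(max_n, n)
        scale = 10.0 ** rng.integers(-1, 3)
        pts = rng.uniform(-scale, scale, size=(n, 2))
        if rng.random() < 0.2:  # grid-snapped sets exercise collinear ties
            snapped = np.round(pts)
            if np.unique(snapped, axis=0).shape[0] >= 3:
                pts = snapped

        cal = geometry.caliper_length(pts)
        errs["caliper"] = max(errs["caliper"], abs(cal - brute_force_caliper(pts)) / max(scale, 1.0))

        hull = geometry.convex_hull(pts)
        area = geometry.polygon_area(hull)
        if n <= 60:
            bf = brute_force_hull_vertices(pts)
            bf_area = geometry.polygon_area(geometry.convex_hull(bf)) if bf.shape[0] >= 3 else 0.0
            errs["hull_area"] = max(errs["hull_area"], abs(area - bf_area) / max(scale**2, 1.0))
            hull_set = {tuple(np.round(p, 7)) for p in hull}
            bf_set = {tuple(np.round(p, 7)) for p in bf}
            if hull.shape[0] >= 3 and not hull_set <= bf_set:
                hull_vertex_mismatch += 1
        else:
            sp = SciPyHull(pts)
            errs["hull_area"] = max(errs["hull_area"], abs(area - sp.volume) / max(scale**2, 1.0))

        _, rect_area = geometry.min_area_rectangle(pts)
        sweep = angle_sweep_rectangle_area(geometry.convex_hull(pts))
        rel = max(scale**2, 1.0)
        # the sweep is an upper bound on a 0.1 deg grid; exact optimum <= sweep
        errs["rect"] = max(
            errs["rect"],
            max(rect_area - sweep - 1e-6, 0.0) / rel,
            max(area - rect_area, 0.0) / rel,  # hull area <= rectangle area
        )

        mec = geometry.min_enclosing_circle(pts, seed=int(rng.integers(2**31)))
        hull_pts = geometry.convex_hull(pts)  # MEC is determined by hull points
        bf_r = brute_force_mec_radius(hull_pts)
        errs["mec"] = max(errs["mec"], abs(mec.radius - bf_r) / max(scale, 1.0))

    return {
        "n_sets": n_sets,
        "max_set_size": max_n,
        "max_rel_error": max(errs.values()),
        "per_primitive": errs,
        "hull_vertex_mismatches": hull_vertex_mismatch,
    }


def _digital_disk(radius: int = 50):
    side = 2 * radius + 11
    yy, xx = np.mgrid[0:side, 0:side]
    c = side // 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def analytic_shape_suite() -> dict:
    """Digital disk (r=50) and 10x10 square against closed forms."""
    from skimage.measure import label

    disk = _digital_disk(50)
    pts = mask_points(disk)
    area = float(disk.sum())
    cal = geometry.caliper_length(pts)
    perim = trace_perimeter(label(disk))
    bp = boundary_points(disk).shape[0]
    out = {
        "disk_area_rel_err": abs(area - math.pi * 50**2) / (math.pi * 50**2),
        "disk_roundness": 4 * area / (math.pi * cal**2),
        "disk_perimeter_rel_err": abs(perim - 2 * math.pi * 50) / (2 * math.pi * 50),
        "disk_bpr": bp / (math.pi * (cal / 2) ** 2),
        "disk_bpr_rel_err": abs(bp / (math.pi * (cal / 2) ** 2) - 2 / 50.0) / (2 / 50.0),
    }
    sq = np.zeros((14, 14), dtype=bool)
    sq[2:12, 2:12] = True
    spts = mask_points(sq)
    hull = geometry.convex_hull(spts)
    out.update(
        square_area=float(sq.sum()),
        square_hull_perimeter=geometry.polygon_perimeter(hull),
        square_caliper=geometry.caliper_length(spts),
        square_trace_perimeter=trace_perimeter(label(sq)),
    )
    return out


def otsu_equivalence(seed: int = 0, n_hist: int = 1000) -> dict:
    """Implementation vs exhaustive 255-split search on random histograms."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_hist):
        kind = rng.integers(3)
        if kind == 0:
            h = rng.integers(0, 50, size=256).astype(float)
        elif kind == 1:  # sparse
            h = np.zeros(256)
            idx = rng.choice(256, size=rng.integers(2, 10), replace=False)
            h[idx] = rng.integers(1, 1000, size=idx.size)
        else:  # bimodal
            h = np.zeros(256)
            for mu in rng.integers(0, 256, size=2):
                x = np.clip(rng.normal(mu, rng.uniform(3, 30), 2000), 0, 255)
                h += np.bincount(x.astype(int), minlength=256)[:256]
        if np.count_nonzero(h) < 2:
            h[[0, 255]] += 1
        t = otsu_threshold(h)

        # exhaustive search over every split
        total = h.sum()
        levels = np.arange(256.0)
        best_t, best_v = 0, -1.0
        for cand in range(255):
            w0 = h[: cand + 1].sum()
            w1 = total - w0
            if w0 == 0 or w1 == 0:
                v = 0.0
            else:
                m0 = (h[: cand + 1] * levels[: cand + 1]).sum() / w0
                m1 = (h[cand + 1 :] * levels[cand + 1 :]).sum() / w1
                v = w0 * w1 * (m0 - m1) ** 2
            if v > best_v + 1e-9:
                best_v, best_t = v, cand
        mismatches += int(t != best_t)
    return {"n_histograms": n_hist, "mismatches": mismatches}


def _default_trial(seed: int) -> tuple:
    """The shared noisy evaluation trial: >=100 images, 4 timepoints."""
    cfg = TrialConfig(
        n_varieties=9,
        plots_unstressed=1,
        plots_treated=2,
        n_individuals=27,
        days=(-7, 7, 14, 28),
        views=("vertical", "horizontal"),
        seed=seed,
    )
    ds = generate_trial(cfg)
    return cfg, ds


def trial_invariants_and_jaccard(seed: int = 0) -> dict:
    """Containment/Jung invariants and Jaccard recovery on a noisy trial."""
    _, ds = _default_trial(seed)
    jaccards = []
    violations = {
        "area_gt_hull_count": 0,
        "hull_area_gt_rect": 0,
        "caliper_gt_mec": 0,
        "jung_bound": 0,
        "hull_perim_gt_trace": 0,
    }
    n_images = 0
    jung = 2.0 / math.sqrt(3.0)
    for key, image in ds.images.items():
        _, truth_mask = ds.truth[key]
        res = segment(image)
        jaccards.append(jaccard(res.roi.pixels, truth_mask))
        if res.n_components == 0:
            continue
        n_images += 1
        obj = res.roi.pixels
        pts = mask_points(obj)
        hull = geometry.convex_hull(pts)
        hull_count = rasterized_hull_count(obj, hull)
        hull_area = geometry.polygon_area(hull)
        _, rect_area = geometry.min_area_rectangle(pts)
        cal = geometry.caliper_length(pts) if pts.shape[0] >= 2 else 0.0
        mec = geometry.min_enclosing_circle(pts, seed=0)
        tol = 1e-9
        if obj.sum() > hull_count + tol:
            violations["area_gt_hull_count"] += 1
        if hull_area > rect_area + 1e-6:
            violations["hull_area_gt_rect"] += 1
        if cal > mec.diameter + 1e-6:
            violations["caliper_gt_mec"] += 1
        if mec.diameter > jung * cal + 1e-6:
            violations["jung_bound"] += 1
        if geometry.polygon_perimeter(hull) > trace_perimeter(res.labels) + 1e-6:
            violations["hull_perim_gt_trace"] += 1
    return {
        "n_images": len(jaccards),
        "n_nonempty": n_images,
        "median_jaccard": float(np.median(jaccards)),
        "min_jaccard": float(np.min(jaccards)),
        "violations": violations,
        "total_violations": sum(violations.values()),
    }


def kruskal_wallis_checks(
    seed: int = 0,
    n_datasets: int = 50,
    n_perm: int = 10_000,
    n_null_trials: int = 200,
) -> dict:
    """H example, permutation-reference agreement, simulated type-I error."""
    h_example, _, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])

    rng = np.random.default_rng([seed, 10])
    max_z = 0.0
    h_mismatch = 0
    for _ in range(n_datasets):
        k = int(rng.integers(2, 5))
        groups = [
            np.round(rng.normal(rng.normal(0, 0.4), 1, size=int(rng.integers(5, 12))), 1)
            for _ in range(k)
        ]
        h_own, _, _ = kruskal_wallis(groups)
        h_scipy = sps.kruskal(*groups).statistic
        if abs(h_own - h_scipy) > 1e-9:
            h_mismatch += 1
        # common random numbers: both H implementations score the same
        # permutations, so any p difference is an H discrepancy
        perm_seed = int(rng.integers(2**31))
        p_own = permutation_kw_p(
            groups, n_perm, np.random.default_rng(perm_seed), True
        )
        p_orc = permutation_kw_p(
            groups, n_perm, np.random.default_rng(perm_seed), False
        )
        se = math.sqrt(
            p_own * (1 - p_own) / n_perm + p_orc * (1 - p_orc) / n_perm
        )
        max_z = max(max_z, abs(p_own - p_orc) / max(se, 1e-6))

    # Type-I error on zero-effect simulated trials (42 plants, day +14).
    # The panel is homogeneous (identical variety parameters): in the full
    # stratified design every treatment group carries the same variety
    # composition, which makes the pooled rank test conservative; the
    # calibration check needs an exchangeable null.
    from .synth import VarietyParams

    null_stress = StressModel(area_shrink_per_day=0.0, yellowing_per_day=0.0)
    rejections = 0
    for t in range(n_null_trials):
        cfg = TrialConfig(
            n_varieties=6,
            n_individuals=42,
            days=(14,),
            views=("vertical",),
            seed=int(np.random.default_rng([seed, 20, t]).integers(2**31)),
        )
        ds = generate_trial(
            cfg,
            varieties=[VarietyParams() for _ in range(6)],
            stress=null_stress,
            render=False,
        )
        m = ds.manifest
        groups = [
            g["true_area_mm2"].to_numpy()
            for _, g in m.groupby("treatment")
        ]
        _, _, p = kruskal_wallis(groups)
        rejections += int(p < 0.05)
    return {
        "h_example": h_example,
        "h_mismatches_vs_scipy": h_mismatch,
        "max_perm_z": max_z,
        "n_datasets": n_datasets,
        "type1_rate": rejections / n_null_trials,
        "n_null_trials": n_null_trials,
    }


def screening_power_day14(seed: int = 0, n_replicates: int = 100) -> dict:
    """Power of the day +14 treatment screen with the default stress model.

    Each replicate renders a reduced trial keeping the 2:5 plot design
    (6 varieties x 7 plots = 42 plants, vertical view, day +14 only), runs
    segmentation + trait extraction + Kruskal–Wallis screening, and
    records whether the projected-area trait is flagged at the 0.005
    image-trait level.
    """
    stress = StressModel()  # defaults: shrink 0.05/day, yellowing on
    flagged_area = 0
    flagged_all_area_traits = 0
    for rep in range(n_replicates):
        cfg = TrialConfig(
            n_varieties=6,
            n_individuals=42,
            days=(14,),
            views=("vertical",),
            image_size=(160, 160),
            px_per_mm=0.6,
            seed=int(np.random.default_rng([seed, 30, rep]).integers(2**31)),
        )
        ds = generate_trial(cfg, stress=stress)
        traits = extract_trial_traits(ds)  # carries treatment/stage metadata
        long = to_long_table(traits, TRAIT_NAMES)
        screen = build_screening_tables(long, groupings=("treatment",))
        area_row = screen[screen["trait_name"] == "area"]
        flagged_area += int(bool(area_row["significant"].all()) and len(area_row))
        area_cat = screen[
            screen["trait_name"].isin(
                ["area", "object_sum_area", "caliper_length",
                 "convex_hull_area", "min_area_rectangle_area"]
            )
        ]
        flagged_all_area_traits += int(bool(area_cat["significant"].all()))
    return {
        "n_replicates": n_replicates,
        "power_area": flagged_area / n_replicates,
        "power_all_area_traits": flagged_all_area_traits / n_replicates,
    }


def _embedding_trial(seed: int, stress: StressModel):
    cfg = TrialConfig(
        n_varieties=16,
        n_individuals=112,
        days=(28,),
        views=("vertical",),
        seed=seed,
    )
    ds = generate_trial(cfg, stress=stress)
    return extract_trial_traits(ds)


def tsne_separation_suite(seed: int = 0, n_seeds: int = 5) -> dict:
    """Treatment silhouette of the all-13-trait t-SNE at end of recovery.

    Stressed trial (default effects) vs zero-effect trial, each embedded
    with ``n_seeds`` t-SNE seeds; also the best single-category PCA
    silhouette on the stressed trial for comparison.
    """
    stressed = _embedding_trial(seed + 1, StressModel())
    null = _embedding_trial(
        seed + 2, StressModel(area_shrink_per_day=0.0, yellowing_per_day=0.0)
    )
    out: dict = {}
    for name, traits in (("stress", stressed), ("null", null)):
        fm = build_feature_matrix(traits, subset="all13")
        labels = fm.labels["treatment"].to_numpy()
        sils = []
        for s in range(n_seeds):
            emb = tsne(fm, perplexity=30, dim=2, seed=seed * 1000 + s)
            sils.append(cluster_separation(emb, labels))
        out[f"tsne_sil_{name}"] = sils
        out[f"tsne_sil_{name}_median"] = float(np.median(sils))
    fm = build_feature_matrix(stressed, subset="all13")
    pca_sils = {}
    for subset in ("area", "boundary", "color"):
        fms = build_feature_matrix(stressed, subset=subset)
        emb = pca(fms, n_components=2)
        pca_sils[subset] = cluster_separation(
            emb, fms.labels["treatment"].to_numpy()
        )
    out["pca_category_sil"] = pca_sils
    out["best_pca_category_sil"] = float(max(pca_sils.values()))
    out["n_rows_stress"] = int(fm.values.shape[0])
    return out


def tsne_calibration_check(seed: int = 0, n: int = 200, d: int = 13,
                           perplexity: float = 30.0) -> dict:
    """Max deviation of row-conditional perplexity from the target, bits."""
    rng = np.random.default_rng(seed)
    x = np.vstack(
        [rng.normal(0, 1, (n // 2, d)), rng.normal(3, 1.5, (n - n // 2, d))]
    )
    p_cond, _ = perplexity_calibration(x, perplexity)
    dev = []
    for i in range(n):
        row = p_cond[i][p_cond[i] > 0]
        h_bits = float(-(row * np.log2(row)).sum())
        dev.append(abs(h_bits - math.log2(perplexity)))
    return {"n": n, "max_dev_bits": float(np.max(dev))}
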