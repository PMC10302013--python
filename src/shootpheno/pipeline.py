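"""End-to-end orchestration: simulate -> preprocess -> segment -> extract
-> filter -> test -> embed.

Stage boundaries follow the four processes of a phenotyping-platform
workflow (data acquisition, preprocessing, data processing, data
analysis); every intermediate artifact is a plain CSV/PNG so any stage can
be inspected or replaced.  All randomness flows from one root seed, split
per stage with ``numpy`` seed sequences.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .embedding import (
    TRAIT_SUBSETS,
    build_feature_matrix,
    cluster_separation,
    pca,
    tsne,
)
from .preprocess import ObstacleRules, exclude_obstacles
from .segmentation import SegmentationParams, jaccard, segment
from .shape_traits import TRAIT_NAMES, extract_traits
from .stats import (
    build_screening_tables,
    pearson_correlation,
    quantile_outlier_filter,
    to_long_table,
)
from .synth import StressModel, TrialConfig, TrialDataset, generate_trial

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "extract_trial_traits",
    "run_pipeline",
    "validate_against_truth",
    "TIMEPOINT_CLASSES",
]

# panels a-d of the per-stage embedding figures
TIMEPOINT_CLASSES = {
    "before": lambda d: d <= 0,
    "after_treatment": lambda d: 0 < d <= 14,
    "recovering": lambda d: 14 < d <= 21,
    "after_recovery": lambda d: d > 21,
}


@dataclass
class PipelineConfig:
    """Validated run configuration; every field has a schema'd default."""

    seed: int = None  # required — no silent default randomness
    out_dir: str = "pipeline_out"
    trial: dict = field(default_factory=dict)
    stress: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)  # obstacle rules
    segmentation: dict = field(default_factory=dict)
    traits: dict = field(default_factory=dict)  # object_mode, circumference_mode
    color: dict = field(default_factory=lambda: {"mode": "lab8"})
    stats: dict = field(
        default_factory=lambda: {
            "alpha_hand": 0.05,
            "alpha_image": 0.005,
            "taus": [0.05, 0.95],
        }
    )
    embedding: dict = field(
        default_factory=lambda: {"perplexity": 30, "dim": 2, "subsets": ["all13"]}
    )
    write_images: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an integer 'seed'")
        self.seed = int(self.seed)
        mode = self.color.get("mode", "lab8")
        if mode not in ("lab8", "rgb"):
            raise ValueError(f"color.mode must be lab8 or rgb, got {mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def trial_config(self) -> TrialConfig:
        return TrialConfig(seed=self.seed, **self.trial)

    def stress_model(self) -> StressModel:
        return StressModel(**self.stress)

    def obstacle_rules(self) -> ObstacleRules | None:
        """Obstacle-exclusion rules from the ``preprocess:`` config key.

        Boxes are {lo: [r,g,b], hi: [r,g,b]} dicts; zones are half-open
        [row0, row1, col0, col1] rectangles.  Returns None when no rules
        are configured.
        """
        if not self.preprocess:
            return None
        from .preprocess import ColorBox

        def box(d):
            return ColorBox(tuple(d["lo"]), tuple(d["hi"]))

        return ObstacleRules(
            color_boxes=[box(b) for b in self.preprocess.get("color_boxes", [])],
            zones=[tuple(z) for z in self.preprocess.get("zones", [])],
            margin=int(self.preprocess.get("margin", 0)),
            foreground=(
                box(self.preprocess["foreground"])
                if "foreground" in self.preprocess
                else None
            ),
        )


@dataclass
class RunManifest:
    """Per-stage record of outputs, row counts and warnings."""

    seed: int
    version: str = ""
    stages: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict | None = None,
               rows: int | None = None, warnings: list | None = None) -> None:
        entry = {
            "stage": stage,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "rows": rows,
            "warnings": warnings or [],
            "outputs": {},
        }
        for name, path in (outputs or {}).items():
            path = Path(path)
            digest = hashlib.sha256(path.read_bytes()).hexdigest() if path.exists() else None
            entry["outputs"][name] = {"path": str(path), "sha256": digest}
        self.stages.append(entry)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def extract_trial_traits(
    ds: TrialDataset,
    seg_params: SegmentationParams | None = None,
    obstacle_rules: ObstacleRules | None = None,
    object_mode: str = "union",
    circumference_mode: str = "perimeter",
    color_mode: str = "lab8",
    mec_seed: int = 0,
) -> pd.DataFrame:
    """Segment every in-memory trial image and extract the 13 traits."""
    rows = []
    for key, image in ds.images.items():
        excl = (
            exclude_obstacles(image, obstacle_rules)
            if obstacle_rules is not None
            else None
        )
        result = segment(image, excl, seg_params)
        rec = extract_traits(
            result,
            image,
            object_mode=object_mode,
            circumference_mode=circumference_mode,
            color_mode=color_mode,
            mec_seed=mec_seed,
        )
        row = rec.to_dict()
        plant_id, day, view = key
        row.update(plant_id=plant_id, day=day, view=view)
        rows.append(row)
    return pd.DataFrame(rows)


def validate_against_truth(traits: pd.DataFrame, ds: TrialDataset) -> dict:
    """Correlate image-derived area with simulated ground truth.

    Returns per-stage Pearson correlations of vertical-view area against
    true area, hand-measured height and node counts, plus a segmentation
    Jaccard summary when in-memory truth masks are available.  Raises when
    trait rows and truth ids cannot be reconciled.
    """
    truth_keys = set(ds.truth)
    trait_keys = {
        (r.plant_id, r.day, r.view) for r in traits.itertuples()
    }
    orphans = sorted(trait_keys - truth_keys)
    if orphans:
        raise ValueError(
            f"{len(orphans)} trait rows have no matching truth record; "
            f"first orphans: {orphans[:5]}"
        )

    traits = traits.copy()
    traits["true_area_mm2"] = [
        ds.truth[(r.plant_id, r.day, r.view)][0].true_area_mm2
        for r in traits.itertuples()
    ]
    hand = ds.hand_measurements.set_index(["plant_id", "day"])
    traits["height_mm"] = [
        hand.loc[(r.plant_id, r.day), "height_mm"] for r in traits.itertuples()
    ]
    traits["nodes_total"] = [
        hand.loc[(r.plant_id, r.day), "nodes_total"] for r in traits.itertuples()
    ]

    report: dict = {"per_stage": {}}
    vert = traits[traits["view"] == "vertical"]
    for stage, sub in (vert if len(vert) else traits).groupby("stage"):
        report["per_stage"][stage] = {
            "r_area_vs_true_area": pearson_correlation(
                sub["area"], sub["true_area_mm2"]
            ),
            "r_area_vs_height": pearson_correlation(sub["area"], sub["height_mm"]),
            "r_area_vs_nodes_total": pearson_correlation(
                sub["area"], sub["nodes_total"]
            ),
        }

    jaccards = []
    for key, image in ds.images.items():
        state, mask = ds.truth[key]
        if mask is None:
            continue
        res = segment(image)
        jaccards.append(jaccard(res.roi.pixels, mask))
    if jaccards:
        report["segmentation_jaccard"] = {
            "median": float(np.median(jaccards)),
            "min": float(np.min(jaccards)),
            "n_images": len(jaccards),
        }
    return report


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage; artifacts land under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, version=__version__)

    # resolved config is written next to the outputs before any work
    resolved = out / "config.resolved.yaml"
    resolved.write_text(yaml.safe_dump(dataclasses.asdict(config)))
    manifest.record("configure", {"config": resolved})

    # --- data acquisition (simulation) ---
    trial_cfg = config.trial_config()
    stress = config.stress_model()
    ds = generate_trial(trial_cfg, stress=stress,
                        out_dir=out / "trial" if config.write_images else None)
    manifest.record("simulate", rows=len(ds.manifest))

    # --- preprocessing + data processing: segmentation and traits ---
    seg_params = SegmentationParams(**config.segmentation)
    traits = extract_trial_traits(
        ds,
        seg_params=seg_params,
        obstacle_rules=config.obstacle_rules(),
        object_mode=config.traits.get("object_mode", "union"),
        circumference_mode=config.traits.get("circumference_mode", "perimeter"),
        color_mode=config.color.get("mode", "lab8"),
        mec_seed=config.seed,
    )
    traits_path = out / "traits.csv"
    traits.to_csv(traits_path, index=False)
    manifest.record("extract", {"traits": traits_path}, rows=len(traits))

    # --- data analysis: outlier filter, screening, validation, embeddings ---
    long = to_long_table(traits, TRAIT_NAMES)
    taus = tuple(config.stats.get("taus", (0.05, 0.95)))
    filtered, report = quantile_outlier_filter(long, taus=taus)
    filtered_path = out / "traits_filtered.csv"
    filtered.to_csv(filtered_path, index=False)
    report.lines.to_csv(out / "outlier_lines.csv", index=False)
    manifest.record(
        "filter",
        {"filtered": filtered_path},
        rows=len(filtered),
        warnings=[f"removed {report.n_removed} outlier rows"],
    )

    screening = build_screening_tables(
        filtered,
        alpha_image=config.stats.get("alpha_image", 0.005),
        alpha_hand=config.stats.get("alpha_hand", 0.05),
    )
    screening_path = out / "screening.csv"
    screening.to_csv(screening_path, index=False)
    manifest.record("stats", {"screening": screening_path}, rows=len(screening))

    validation = validate_against_truth(traits, ds)
    (out / "validation.json").write_text(json.dumps(validation, indent=2))
    manifest.record("validate", {"validation": out / "validation.json"})

    emb_rows = []
    perplexity = float(config.embedding.get("perplexity", 30))
    dim = int(config.embedding.get("dim", 2))
    for subset in config.embedding.get("subsets", ["all13"]):
        for cls_name, pred in TIMEPOINT_CLASSES.items():
            sub = traits[traits["day"].map(pred)]
            if sub.empty:
                continue
            fm = build_feature_matrix(sub, subset=subset)
            if fm.values.shape[0] < 4 or fm.values.shape[1] == 0:
                continue
            emb = pca(fm, n_components=min(dim, fm.values.shape[1]))
            sil = cluster_separation(emb, fm.labels["treatment"].to_numpy())
            emb_rows.append(
                {
                    "subset": subset,
                    "timepoint_class": cls_name,
                    "method": "pca",
                    "silhouette_treatment": sil,
                    "n_rows": fm.values.shape[0],
                }
            )
            if (
                subset == "all13"
                and fm.values.shape[0] > 3 * perplexity
            ):
                emb_t = tsne(fm, perplexity=perplexity, dim=dim, seed=config.seed)
                sil_t = cluster_separation(
                    emb_t, fm.labels["treatment"].to_numpy()
                )
                emb_rows.append(
                    {
                        "subset": subset,
                        "timepoint_class": cls_name,
                        "method": "tsne",
                        "silhouette_treatment": sil_t,
                        "n_rows": fm.values.shape[0],
                    }
                )
                coords = pd.DataFrame(
                    emb_t.coordinates, columns=["dim1", "dim2"]
                )
                coords = pd.concat(
                    [fm.labels.reset_index(drop=True), coords], axis=1
                )
                coords.to_csv(
                    out / f"tsne_{subset}_{cls_name}.csv", index=False
                )
                if config.make_plots:
                    _scatter(
                        coords, out / f"tsne_{subset}_{cls_name}.png",
                        f"t-SNE {subset} {cls_name}"
                    )
    emb_path = out / "embeddings.csv"
    pd.DataFrame(emb_rows).to_csv(emb_path, index=False)
    manifest.record("embed", {"embeddings": emb_path}, rows=len(emb_rows))

    manifest.save(out / "run_manifest.json")
    return manifest


def _scatter(coords: pd.DataFrame, path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    # figure convention: red = unstressed, blue = drought-treated
    palette = {"unstressed": "tab:red", "drought": "tab:blue"}
    for name, sub in coords.groupby("treatment"):
        ax.scatter(
            sub["dim1"], sub["dim2"], s=12,
            c=palette.get(name, "gray"), label=name
        )
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
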