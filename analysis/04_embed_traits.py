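#!/usr/bin/env python
"""Embed the 13-trait space per timepoint class and score separation.

PCA per trait category and t-SNE (perplexity adapted to row count) over
all 13 traits, one embedding per timepoint class (before / after
treatment / recovering / after recovery), with the treatment silhouette
quantifying drought discrimination.  Writes results/embeddings.csv and
scatter PNGs under results/.
"""

from pathlib import Path

import pandas as pd

from shootpheno.embedding import (
    build_feature_matrix,
    cluster_separation,
    pca,
    tsne,
)
from shootpheno.pipeline import TIMEPOINT_CLASSES, _scatter

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 20230615

if __name__ == "__main__":
    traits = pd.read_csv(RESULTS / "traits.csv")
    rows = []
    for cls_name, pred in TIMEPOINT_CLASSES.items():
        sub = traits[traits["day"].map(pred)]
        if sub.empty:
            continue
        for subset in ("area", "boundary", "color", "all13"):
            fm = build_feature_matrix(sub, subset=subset)
            labels = fm.labels["treatment"].to_numpy()
            emb = pca(fm, n_components=2)
            rows.append(
                dict(timepoint=cls_name, subset=subset, method="pca",
                     silhouette=cluster_separation(emb, labels),
                     n=fm.values.shape[0])
            )
            if subset == "all13":
                perp = min(30.0, fm.values.shape[0] / 3 - 1)
                emb_t = tsne(fm, perplexity=perp, seed=SEED)
                sil = cluster_separation(emb_t, labels)
                rows.append(
                    dict(timepoint=cls_name, subset=subset, method="tsne",
                         silhouette=sil, n=fm.values.shape[0])
                )
                coords = pd.concat(
                    [fm.labels.reset_index(drop=True),
                     pd.DataFrame(emb_t.coordinates, columns=["dim1", "dim2"])],
                    axis=1,
                )
                SCRATCH.mkdir(exist_ok=True)
                _scatter(coords, SCRATCH / f"tsne_{cls_name}.png",
                         f"t-SNE all13 {cls_name}")
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "embeddings.csv", index=False)
    print("treatment silhouettes per timepoint class and trait subset:")
    print(table.round(3).to_string(index=False))
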