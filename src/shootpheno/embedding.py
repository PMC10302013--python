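"""Low-dimensional embeddings of the 13-trait space.

PCA per trait category (area / boundary / color) and t-SNE over all 13
traits quantify whether drought-treated and unstressed plants occupy
separable regions of trait space at each timepoint.  Columns are z-scored
first — the traits mix px, px² and squared-level units, so unscaled
variance would be meaningless.  Rows with any missing trait are dropped,
never imputed.

The t-SNE implementation is the exact O(n²) algorithm: per-row Gaussian
bandwidths calibrated by binary search so each conditional distribution
has the target perplexity; symmetrized affinities; Student-t (1 df)
low-dimensional kernel; KL-divergence gradient descent with early
exaggeration and momentum.  Trait tables here have a few hundred rows per
timepoint, where the exact gradient is fast and deterministic for a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .shape_traits import TRAIT_NAMES, AREA_TRAITS, BOUNDARY_TRAITS, COLOR_TRAITS

__all__ = [
    "FeatureMatrix",
    "EmbeddingResult",
    "build_feature_matrix",
    "pca",
    "tsne",
    "perplexity_calibration",
    "cluster_separation",
    "TRAIT_SUBSETS",
]

TRAIT_SUBSETS = {
    "area": AREA_TRAITS,
    "boundary": BOUNDARY_TRAITS,
    "color": COLOR_TRAITS,
    "all13": TRAIT_NAMES,
}


@dataclass
class FeatureMatrix:
    """Z-scored trait matrix with row labels (treatment etc.)."""

    values: np.ndarray  # rows x traits, unit-variance columns
    columns: list[str]
    labels: pd.DataFrame  # one row per matrix row
    subset: str = "all13"


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # rows x 2
    method: str
    explained_variance: np.ndarray | None = None  # pca only, fractions
    seed: int | None = None
    perplexity: float | None = None
    dropped_rows: int = 0


def build_feature_matrix(
    records: pd.DataFrame, subset: str = "all13"
) -> FeatureMatrix:
    """Per-image wide trait table -> z-scored matrix for one embedding.

    Rows with any missing selected trait are dropped; zero-variance
    columns are dropped with a warning entry in ``labels.attrs``.
    """
    traits = [t for t in TRAIT_SUBSETS[subset] if t in records.columns]
    if not traits:
        raise ValueError(f"no trait columns for subset {subset!r}")
    sub = records.dropna(subset=traits).reset_index(drop=True)
    x = sub[traits].to_numpy(dtype=float)
    sd = x.std(axis=0)
    keep = sd > 0
    dropped_cols = [t for t, k in zip(traits, keep) if not k]
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    label_cols = [
        c
        for c in ("plant_id", "variety", "treatment", "stage", "day", "view")
        if c in sub.columns
    ]
    labels = sub[label_cols].copy()
    labels.attrs["dropped_columns"] = dropped_cols
    labels.attrs["dropped_rows"] = len(records) - len(sub)
    return FeatureMatrix(
        values=x,
        columns=[t for t, k in zip(traits, keep) if k],
        labels=labels,
        subset=subset,
    )


def pca(fm: FeatureMatrix, n_components: int = 2) -> EmbeddingResult:
    """Principal components of the z-scored matrix.

    Eigendecomposition of the column covariance; scores are projections
    onto the top eigenvectors.  The sign of each component is fixed by
    making its largest-magnitude loading positive, so results do not
    depend on LAPACK sign conventions or row order.
    """
    x = fm.values
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    n_components = min(n_components, x.shape[1])
    cov = np.cov(x, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    frac = evals / evals.sum() if evals.sum() > 0 else evals
    scores = (x - x.mean(axis=0)) @ evecs[:, :n_components]
    return EmbeddingResult(
        coordinates=scores,
        method="pca",
        explained_variance=frac[:n_components],
        dropped_rows=fm.labels.attrs.get("dropped_rows", 0),
    )


def _entropy_and_p(d2_row: np.ndarray, beta: float):
    """Shannon entropy (nats) and probabilities of one conditional row."""
    p = np.exp(-d2_row * beta)
    s = p.sum()
    if s <= 0:
        return 0.0, np.zeros_like(p)
    p /= s
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    return h, p


def perplexity_calibration(
    x: np.ndarray, perplexity: float, tol: float = 1e-7, max_iter: int = 100
):
    """Per-row Gaussian bandwidths matched to a target perplexity.

    Binary search on the precision beta_i = 1/(2 sigma_i^2) of each row's
    conditional distribution p_{j|i} until its entropy equals
    log(perplexity) within ``tol`` nats.  Returns (P_conditional, betas);
    the diagonal of P is zero.
    """
    n = x.shape[0]
    d2 = np.square(x[:, None, :] - x[None, :, :]).sum(-1)
    target = math.log(perplexity)
    p_cond = np.zeros((n, n))
    betas = np.ones(n)
    for i in range(n):
        row = np.delete(d2[i], i)
        beta, lo, hi = 1.0, 0.0, math.inf
        for _ in range(max_iter):
            h, p = _entropy_and_p(row, beta)
            if abs(h - target) < tol:
                break
            if h > target:  # too flat -> narrow the kernel
                lo = beta
                beta = beta * 2.0 if hi == math.inf else (beta + hi) / 2.0
            else:
                hi = beta
                beta = beta / 2.0 if lo == 0.0 else (beta + lo) / 2.0
        betas[i] = beta
        p_cond[i, np.arange(n) != i] = p
    return p_cond, betas


def tsne(
    fm: FeatureMatrix | np.ndarray,
    perplexity: float = 30.0,
    dim: int = 2,
    seed: int = 0,
    n_iter: int = 1000,
    learning_rate: float = 200.0,
    early_exaggeration: float = 12.0,
) -> EmbeddingResult:
    """t-SNE embedding (exact gradient, deterministic for a fixed seed)."""
    x = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    n = x.shape[0]
    if perplexity >= n / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} rows; "
            f"use a value below n/3 = {n / 3:.0f}"
        )
    p_cond, _ = perplexity_calibration(x, perplexity)
    p = (p_cond + p_cond.T) / (2.0 * n)
    p = np.maximum(p, 1e-12)

    rng = np.random.default_rng(seed)
    y = rng.normal(scale=1e-4, size=(n, dim))
    update = np.zeros_like(y)
    gains = np.ones_like(y)
    exag_iters = 250
    p_run = p * early_exaggeration
    for it in range(n_iter):
        if it == exag_iters:
            p_run = p
        diff = y[:, None, :] - y[None, :, :]
        d2 = np.square(diff).sum(-1)
        num = 1.0 / (1.0 + d2)
        np.fill_diagonal(num, 0.0)
        q = np.maximum(num / num.sum(), 1e-12)
        w = (p_run - q) * num
        grad = 4.0 * ((w.sum(1)[:, None] * y) - w @ y)
        momentum = 0.5 if it < exag_iters else 0.8
        same_sign = np.sign(grad) == np.sign(update)
        gains = np.where(same_sign, gains * 0.8, gains + 0.2)
        gains = np.maximum(gains, 0.01)
        update = momentum * update - learning_rate * gains * grad
        y = y + update
        y = y - y.mean(0)
    return EmbeddingResult(
        coordinates=y,
        method="tsne",
        seed=seed,
        perplexity=perplexity,
        dropped_rows=(
            fm.labels.attrs.get("dropped_rows", 0)
            if isinstance(fm, FeatureMatrix)
            else 0
        ),
    )


def cluster_separation(emb: EmbeddingResult, labels) -> float:
    """Mean silhouette of the embedding under the given labels.

    Euclidean metric; NaN (missing sentinel) when fewer than two distinct
    labels are present.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != emb.coordinates.shape[0]:
        raise ValueError("labels length differs from embedding rows")
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(silhouette_score(emb.coordinates, labels, metric="euclidean"))
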