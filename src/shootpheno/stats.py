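"""Screening statistics over the long trait table.

Three stages mirror a standard drought-screen analysis: tail-quantile
outlier removal per trait cell via linear quantile regression on day,
Kruskal–Wallis rank tests per (trait, view, stage) for treatment and for
variety groupings, and Pearson correlations validating image-derived area
against hand measurements.  No multiple-testing adjustment is applied to
the screening tables (raw thresholds are reported, with an optional
Benjamini–Hochberg column that never drives the significance flag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.quantile_regression import QuantReg

logger = logging.getLogger(__name__)

__all__ = [
    "kruskal_wallis",
    "pearson_correlation",
    "quantile_outlier_filter",
    "build_screening_tables",
    "OutlierReport",
    "to_long_table",
]


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Kruskal–Wallis H test over k groups of values.

    Mid-ranks over the pooled sample; H = 12/(N(N+1)) * sum(R_i^2/n_i)
    - 3(N+1), divided by the tie-correction factor 1 - sum(t^3 - t)/(N^3
    - N).  The p-value is the chi-square upper tail with df = k - 1.  When
    every pooled value is identical the statistic is 0 and p is 1 (the
    documented degenerate convention).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("every group must be nonempty")
        if not np.all(np.isfinite(g)):
            raise ValueError("values must be finite")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(groups) - 1

    ranks = sps.rankdata(pooled)  # mid-ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:  # all values identical
        return 0.0, df, 1.0

    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = (12.0 / (n_total * (n_total + 1.0))) * h - 3.0 * (n_total + 1.0)
    h /= correction
    p = float(sps.chi2.sf(h, df))
    return float(h), df, p


def pearson_correlation(x, y) -> float:
    """Product-moment correlation with pairwise deletion of missing rows.

    Returns NaN (a missing sentinel) when either argument has zero
    variance after deletion or fewer than 3 complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class OutlierReport:
    """Per-row keep/remove flags plus the fitted quantile lines per cell."""

    flags: pd.Series = None  # True = kept
    lines: pd.DataFrame = field(default_factory=pd.DataFrame)
    taus: tuple[float, float] = (0.05, 0.95)

    @property
    def n_removed(self) -> int:
        return int((~self.flags).sum())


def _fit_quantile_line(day: np.ndarray, value: np.ndarray, tau: float):
    """Pinball-loss linear fit value ~ day at quantile tau.

    Falls back to the empirical residual quantile about the median-slope
    line when the cell has a single day level or the LP fit fails.
    """
    if np.ptp(day) == 0:
        return 0.0, float(np.quantile(value, tau))
    exog = sm.add_constant(day)
    try:
        res = QuantReg(value, exog).fit(q=tau)
        return float(res.params[1]), float(res.params[0])
    except Exception:  # degenerate cell: residual-quantile fallback
        med = QuantReg(value, exog).fit(q=0.5)
        resid = value - med.predict(exog)
        return float(med.params[1]), float(med.params[0] + np.quantile(resid, tau))


def quantile_outlier_filter(
    table: pd.DataFrame,
    taus: tuple[float, float] = (0.05, 0.95),
    covariate: str = "day",
    cell_keys: tuple[str, ...] = ("trait_name", "view", "stage", "treatment"),
    min_cell: int = 10,
) -> tuple[pd.DataFrame, OutlierReport]:
    """Remove tail observations outside fitted quantile-regression lines.

    Within each ``cell_keys`` cell, linear quantile lines value ~ day are
    fitted at tau_lo and tau_hi; rows strictly below the lower line or
    strictly above the upper line are removed.  Cells with fewer than
    ``min_cell`` observations pass through unfiltered with a warning.
    """
    tau_lo, tau_hi = taus
    if not 0.0 < tau_lo < tau_hi < 1.0:
        raise ValueError("taus must satisfy 0 < tau_lo < tau_hi < 1")
    table = table.reset_index(drop=True)
    keep = pd.Series(True, index=table.index)
    lines = []
    keys = [k for k in cell_keys if k in table.columns]
    for cell, sub in table.groupby(list(keys), dropna=False, observed=True):
        vals = sub["value"].to_numpy(dtype=float)
        days = sub[covariate].to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(days)
        if ok.sum() < min_cell:
            logger.warning("cell %s has %d obs (<%d): passed unfiltered",
                           cell, int(ok.sum()), min_cell)
            continue
        slo, ilo = _fit_quantile_line(days[ok], vals[ok], tau_lo)
        shi, ihi = _fit_quantile_line(days[ok], vals[ok], tau_hi)
        lo = ilo + slo * days
        hi = ihi + shi * days
        tol = 1e-9 * (1.0 + np.abs(vals))
        out = ok & ((vals < lo - tol) | (vals > hi + tol))
        keep.loc[sub.index[out]] = False
        lines.append(
            dict(zip(keys, cell if isinstance(cell, tuple) else (cell,)))
            | {
                "tau_lo": tau_lo,
                "tau_hi": tau_hi,
                "slope_lo": slo,
                "intercept_lo": ilo,
                "slope_hi": shi,
                "intercept_hi": ihi,
                "n_removed": int(out.sum()),
            }
        )
    report = OutlierReport(flags=keep, lines=pd.DataFrame(lines), taus=taus)
    return table[keep].reset_index(drop=True), report


def build_screening_tables(
    table: pd.DataFrame,
    groupings: tuple[str, ...] = ("treatment", "variety"),
    alpha_image: float = 0.005,
    alpha_hand: float = 0.05,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Kruskal–Wallis screening rows per (trait, view, stage, grouping).

    Image traits are flagged at ``alpha_image`` (0.005), hand-measured
    traits (rows whose view is "hand") at ``alpha_hand`` (0.05).  A cell
    with a single group present yields a row with missing H/p.  With
    ``add_bh`` a Benjamini–Hochberg adjusted column is appended for
    reference; the significance flag always uses the raw p.
    """
    rows = []
    for grouping in groupings:
        for (trait, view, stage), sub in table.groupby(
            ["trait_name", "view", "stage"], observed=True
        ):
            sub = sub.dropna(subset=["value"])
            groups = [
                g["value"].to_numpy(dtype=float)
                for _, g in sub.groupby(grouping, observed=True)
                if len(g) > 0
            ]
            alpha = alpha_hand if view == "hand" else alpha_image
            row = {
                "trait_name": trait,
                "view": view,
                "stage": stage,
                "grouping": grouping,
                "n": int(len(sub)),
                "k": len(groups),
                "H": float("nan"),
                "df": len(groups) - 1,
                "p_value": float("nan"),
                "alpha": alpha,
                "significant": False,
            }
            if len(groups) >= 2 and sum(len(g) for g in groups) >= 3:
                h, df, p = kruskal_wallis(groups)
                row.update(H=h, df=df, p_value=p, significant=bool(p < alpha))
            rows.append(row)
    out = pd.DataFrame(rows)
    if add_bh and len(out):
        p = out["p_value"].to_numpy()
        mask = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if mask.sum():
            adj[mask] = sps.false_discovery_control(p[mask], method="bh")
        out["p_bh"] = adj
    return out


def to_long_table(records: pd.DataFrame, trait_names) -> pd.DataFrame:
    """Wide per-image trait table -> long (one row per trait value)."""
    id_cols = [
        c
        for c in ("plant_id", "variety", "plot", "treatment", "stage", "day", "view")
        if c in records.columns
    ]
    long = records.melt(
        id_vars=id_cols,
        value_vars=[t for t in trait_names if t in records.columns],
        var_name="trait_name",
        value_name="value",
    )
    return long
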