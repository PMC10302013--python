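"""Rank tests, correlations and quantile-regression outlier filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from shootpheno.evaluation import permutation_kw_p
from shootpheno.stats import (
    build_screening_tables,
    kruskal_wallis,
    pearson_correlation,
    quantile_outlier_filter,
    to_long_table,
)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(27 / 7)
        assert df == 1

    def test_identical_groups_zero_statistic(self):
        h, _, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_convention(self):
        h, _, p = kruskal_wallis([[5, 5, 5], [5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        groups = [rng.normal(0, 1, 8), rng.normal(0.5, 1, 10), rng.normal(1, 1, 6)]
        h1, _, p1 = kruskal_wallis(groups)
        h2, _, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 5))
            groups = [
                np.round(rng.normal(0, 2, int(rng.integers(4, 15))), 0)
                for _ in range(k)
            ]
            h, df, p = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_permutation_reference_agreement(self, rng):
        """MC p from our H vs an independent rank-variance H, 3 SE band."""
        for _ in range(5):
            groups = [
                np.round(rng.normal(rng.normal(0, 0.4), 1, int(rng.integers(6, 12))), 1)
                for _ in range(int(rng.integers(2, 4)))
            ]
            n_perm = 3000
            p_own = permutation_kw_p(groups, n_perm, np.random.default_rng(1), True)
            p_orc = permutation_kw_p(groups, n_perm, np.random.default_rng(2), False)
            se = math.sqrt(
                p_own * (1 - p_own) / n_perm + p_orc * (1 - p_orc) / n_perm
            )
            assert abs(p_own - p_orc) <= 3 * max(se, 1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_missing_pairs_deleted(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, np.nan, 10]
        assert pearson_correlation(x, y) == pytest.approx(1.0)

    def test_zero_variance_sentinel(self):
        assert math.isnan(pearson_correlation([1, 1, 1], [1, 2, 3]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=20),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_affine_invariance_and_symmetry(self, xs, a, b):
        rng = np.random.default_rng(0)
        x = np.asarray(xs)
        y = rng.normal(0, 1, x.size)
        r = pearson_correlation(x, y)
        if math.isnan(r):
            return
        assert pearson_correlation(y, x) == pytest.approx(r, abs=1e-9)
        assert pearson_correlation(a * x + b, y) == pytest.approx(r, abs=1e-6)


def _long(value, day, **consts):
    df = pd.DataFrame({"value": value, "day": day})
    for k, v in {"trait_name": "area", "view": "vertical", "stage": "V3",
                 "treatment": "unstressed", **consts}.items():
        df[k] = v
    return df


class TestQuantileOutlierFilter:
    def test_points_on_a_line_untouched(self):
        day = np.tile([0.0, 7, 14], 10)
        table = _long(2 * day + 3, day)
        filtered, report = quantile_outlier_filter(table)
        assert report.n_removed == 0
        assert len(filtered) == len(table)

    def test_gross_outlier_removed_with_bounded_collateral(self, rng):
        day = rng.uniform(0, 14, 101)
        value = day + rng.uniform(-1, 1, 101)
        value[0] = day[0] + 50
        table = _long(value, day)
        filtered, report = quantile_outlier_filter(table, taus=(0.05, 0.95))
        assert 0 not in filtered.index or filtered.loc[0, "value"] != value[0]
        assert (filtered["value"] - filtered["day"]).abs().max() < 5
        assert report.n_removed <= math.ceil(101 * 0.10) + 1

    def test_quantile_property(self, rng):
        day = rng.uniform(0, 14, 400)
        value = 3 * day + rng.normal(0, 2, 400)
        table = _long(value, day)
        _, report = quantile_outlier_filter(table, taus=(0.25, 0.75))
        line = report.lines.iloc[0]
        below = (value < line["intercept_lo"] + line["slope_lo"] * day).mean()
        assert below == pytest.approx(0.25, abs=2 / math.sqrt(400))

    def test_small_cell_passes_through(self, caplog):
        table = _long([1.0, 2.0, 3.0], [0.0, 7.0, 14.0])
        with caplog.at_level("WARNING"):
            filtered, report = quantile_outlier_filter(table)
        assert len(filtered) == 3 and report.n_removed == 0

    def test_idempotent_on_clean_data(self, rng):
        day = rng.uniform(0, 14, 300)
        table = _long(day + rng.normal(0, 1, 300), day)
        once, r1 = quantile_outlier_filter(table)
        twice, r2 = quantile_outlier_filter(once)
        assert r2.n_removed <= r1.n_removed

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            quantile_outlier_filter(_long([1.0] * 12, [0.0] * 12), taus=(0.9, 0.1))


class TestScreeningTables:
    def _table(self, rng, effect=0.0):
        rows = []
        for trait in ("area", "caliper_length"):
            for treat, n in (("unstressed", 12), ("drought", 30)):
                shift = effect if treat == "drought" else 0.0
                for v in rng.normal(shift, 1, n):
                    rows.append(
                        {
                            "trait_name": trait,
                            "view": "vertical",
                            "stage": "V3",
                            "treatment": treat,
                            "variety": f"VAR{rng.integers(3)}",
                            "day": 14,
                            "value": v,
                        }
                    )
        return pd.DataFrame(rows)

    def test_df_is_k_minus_one(self, rng):
        screen = build_screening_tables(self._table(rng))
        by_grouping = screen.groupby("grouping")["df"].unique()
        assert (by_grouping["treatment"] == [1]).all()
        assert (by_grouping["variety"] == [2]).all()

    def test_single_group_missing_p(self, rng):
        t = self._table(rng)
        t = t[t["treatment"] == "drought"]
        screen = build_screening_tables(t, groupings=("treatment",))
        assert screen["p_value"].isna().all()
        assert not screen["significant"].any()

    def test_strong_effect_flagged_at_0005(self, rng):
        screen = build_screening_tables(self._table(rng, effect=3.0))
        rows = screen[screen["grouping"] == "treatment"]
        assert rows["significant"].all()
        assert (rows["alpha"] == 0.005).all()

    def test_hand_view_uses_005_alpha(self, rng):
        t = self._table(rng)
        t["view"] = "hand"
        screen = build_screening_tables(t)
        assert (screen["alpha"] == 0.05).all()

    def test_bh_column_does_not_drive_flag(self, rng):
        screen = build_screening_tables(self._table(rng, effect=3.0), add_bh=True)
        assert "p_bh" in screen.columns
        flagged = screen[screen["significant"]]
        assert (flagged["p_value"] < flagged["alpha"]).all()


def test_to_long_table_round_trip(rng):
    wide = pd.DataFrame(
        {
            "plant_id": ["a", "b"],
            "treatment": ["unstressed", "drought"],
            "stage": ["V3", "V3"],
            "day": [14, 14],
            "view": ["vertical", "vertical"],
            "area": [10.0, 20.0],
            "roundness": [0.5, 0.6],
        }
    )
    long = to_long_table(wide, ("area", "roundness"))
    assert len(long) == 4
    assert set(long["trait_name"]) == {"area", "roundness"}
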