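"""Synthetic trial generator: growth model, renderer, trial assembly."""

import numpy as np
import pytest

from shootpheno.stats import pearson_correlation
from shootpheno.synth import (
    PlantState,
    RenderError,
    StressModel,
    TrialConfig,
    VarietyParams,
    generate_trial,
    render_plant,
    simulate_growth,
)


class TestSimulateGrowth:
    def test_closed_form_exponential_growth(self):
        v = VarietyParams(base_area_mm2=1000.0, growth_rate=0.1)
        s = StressModel()
        for day in (-7, 0, 7, 14):
            st = simulate_growth(v, s, treated=False, day=day, area_noise=0.0)
            assert st.true_area_mm2 == pytest.approx(
                1000.0 * 1.1 ** (day + 7), rel=1e-12
            )

    def test_zero_effect_treated_equals_unstressed(self):
        v = VarietyParams()
        s = StressModel(area_shrink_per_day=0.0, yellowing_per_day=0.0)
        for day in (-7, 0, 7, 14, 21, 28):
            a = simulate_growth(v, s, True, day, np.random.default_rng(5))
            b = simulate_growth(v, s, False, day, np.random.default_rng(5))
            assert a == b

    def test_treated_area_shrinks_relative_to_unstressed(self):
        v = VarietyParams()
        s = StressModel(area_shrink_per_day=0.05)
        treated = simulate_growth(v, s, True, 14, area_noise=0.0)
        control = simulate_growth(v, s, False, 14, area_noise=0.0)
        assert treated.true_area_mm2 == pytest.approx(
            control.true_area_mm2 * 0.95**14, rel=1e-12
        )

    def test_determinism_same_seed_same_state(self):
        v, s = VarietyParams(), StressModel()
        a = simulate_growth(v, s, True, 14, rng_state=42)
        b = simulate_growth(v, s, True, 14, rng_state=42)
        assert a == b

    def test_day_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_growth(VarietyParams(), StressModel(), False, 99)

    def test_node_counts_ordered(self):
        st = simulate_growth(VarietyParams(), StressModel(), False, 14, 3)
        assert st.node_count_total >= st.node_count_main

    def test_effect_monotonicity_in_shrink_rate(self):
        """Expected day+14 treated area is non-increasing in the shrink rate."""
        v = VarietyParams()
        grid = [0.0, 0.02, 0.05, 0.08]
        means = []
        for shrink in grid:
            s = StressModel(area_shrink_per_day=shrink)
            areas = [
                simulate_growth(
                    v, s, True, 14, np.random.default_rng([7, i])
                ).true_area_mm2
                for i in range(200)
            ]
            means.append(np.mean(areas))
        assert all(a >= b for a, b in zip(means, means[1:]))


class TestRenderPlant:
    def test_mask_count_matches_area(self):
        state = simulate_growth(
            VarietyParams(base_area_mm2=2000.0), StressModel(), False, 7,
            area_noise=0.0,
        )
        cfg = TrialConfig(seed=0)
        _, mask = render_plant(state, "vertical", cfg, 3, color_noise=0.0)
        target = state.true_area_mm2 * cfg.px_per_mm**2
        assert mask.sum() == pytest.approx(target, rel=0.05)

    def test_bit_identical_for_same_seed(self):
        state = simulate_growth(VarietyParams(), StressModel(), False, 0, 1)
        cfg = TrialConfig(seed=0)
        img1, m1 = render_plant(state, "horizontal", cfg, 9)
        img2, m2 = render_plant(state, "horizontal", cfg, 9)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(m1, m2)

    def test_zero_area_gives_empty_mask_with_clutter(self):
        state = PlantState(0, 0.0, 100.0, 2, 3, (70, 170, 60))
        cfg = TrialConfig(seed=0)
        img, mask = render_plant(state, "vertical", cfg, 0)
        assert mask.sum() == 0
        assert img.pixels.std() > 0  # background/pot/strut still drawn

    def test_oversized_plant_raises_named_error(self):
        state = PlantState(0, 5e6, 100.0, 2, 3, (70, 170, 60))
        with pytest.raises(RenderError, match="PLX"):
            render_plant(state, "vertical", TrialConfig(seed=0), 0, plant_id="PLX")

    def test_unknown_view_rejected(self):
        state = PlantState(0, 100.0, 10.0, 1, 1, (70, 170, 60))
        with pytest.raises(ValueError):
            render_plant(state, "oblique", TrialConfig(seed=0), 0)


class TestGenerateTrial:
    def test_full_design_manifest_counts(self):
        """28 varieties x 7 plots trimmed to 180 plants; rows = plants x days x views."""
        cfg = TrialConfig(seed=0)
        ds = generate_trial(cfg, render=False)
        assert ds.manifest["plant_id"].nunique() == 180
        assert len(ds.manifest) == 180 * 6 * 2
        assert len(ds.hand_measurements) == 180 * 6

    def test_small_counting_contract(self):
        cfg = TrialConfig(
            n_varieties=1, plots_unstressed=1, plots_treated=1,
            n_individuals=2, days=(0, 14), views=("vertical",), seed=2,
        )
        ds = generate_trial(cfg)
        assert len(ds.images) == 4

    def test_same_seed_identical_manifest(self):
        cfg = TrialConfig(
            n_varieties=2, plots_unstressed=1, plots_treated=1,
            n_individuals=4, days=(0,), views=("vertical",), seed=5,
        )
        m1 = generate_trial(cfg).manifest
        m2 = generate_trial(cfg).manifest
        assert m1.equals(m2)

    def test_variety_count_mismatch_rejected(self):
        cfg = TrialConfig(
            n_varieties=3, plots_unstressed=1, plots_treated=1,
            n_individuals=6, days=(0,), seed=0,
        )
        with pytest.raises(ValueError, match="variety"):
            generate_trial(cfg, varieties=[VarietyParams()])

    def test_truth_mask_consistent_with_state(self, small_trial):
        cfg, ds = small_trial
        for key in ds.images:
            state, mask = ds.truth[key]
            target = state.true_area_mm2 * cfg.px_per_mm**2
            assert mask.sum() == pytest.approx(target, rel=0.10)

    def test_height_area_correlation_by_construction(self):
        cfg = TrialConfig(
            n_varieties=10, n_individuals=70, days=(-7, 7, 21),
            views=("vertical",), seed=13,
        )
        ds = generate_trial(cfg, render=False)
        merged = ds.manifest.merge(
            ds.hand_measurements, on=["plant_id", "day"], suffixes=("", "_h")
        )
        r = pearson_correlation(merged["true_area_mm2"], merged["height_mm"])
        assert r > 0.5

    def test_drop_pre_treatment_removes_negative_days(self):
        cfg = TrialConfig(
            n_varieties=1, plots_unstressed=1, plots_treated=1,
            n_individuals=2, days=(-7, 0, 14), views=("vertical",),
            drop_pre_treatment=True, seed=0,
        )
        ds = generate_trial(cfg, render=False)
        assert set(ds.manifest["day"]) == {0, 14}

    def test_plot_counts_match_design(self):
        cfg = TrialConfig(seed=4)
        ds = generate_trial(cfg, render=False)
        per_plot = ds.manifest.groupby("plot")["treatment"].first()
        assert (per_plot == "unstressed").sum() == 2
        assert (per_plot == "drought").sum() == 5
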