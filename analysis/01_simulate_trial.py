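#!/usr/bin/env python
"""Simulate a desk-scale drought trial and write its images and tables.

A 9-variety panel (1 unstressed + 2 drought plots, 27 plants) is imaged
from two angles on days -7, +7, +14 and +28 around a 14-day water
deficit.  Outputs under scratch/trial/: PNG images and truth masks, a
manifest CSV and the hand-measurement table.
"""

from pathlib import Path

from shootpheno.synth import TrialConfig, generate_trial

# image/mask PNGs are bulky scratch artifacts; tables land in results/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "trial"

config = TrialConfig(
    n_varieties=9,
    plots_unstressed=1,
    plots_treated=2,
    n_individuals=27,
    days=(-7, 7, 14, 28),
    views=("vertical", "horizontal"),
    seed=20230615,
)

if __name__ == "__main__":
    ds = generate_trial(config, out_dir=OUT)
    n_img = len(ds.manifest)
    treated = (ds.manifest["treatment"] == "drought").sum() // (4 * 2)
    print(f"wrote {n_img} images for 27 plants ({treated} drought-treated) "
          f"under {OUT}")
    print(ds.hand_measurements.groupby(["treatment", "day"])["height_mm"]
          .mean().round(1).to_string())
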