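#!/usr/bin/env python
"""Segment, profile, and classify the simulated sporulating populations.

For the wt-like and degradation-blocked-like scenes from 01: run the full
pipeline (segmentation with the divided sporangium kept whole; membrane-
normalized axial profiles; septum detection; forespore-pole alignment),
report the recovered mis-compartmentalization percentage against the
planted rate, and write the population-average localization profile and
per-cell calls under results/profiles/.

For the undivided polar-cap population: build the random-pole average
profile from 20 randomly selected cell poles, the control used to show
pole-localized enrichment without a septum to orient by.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from polarprof import synthgen as sg
from polarprof.axialprofile import random_pole_profiles
from polarprof.pipeline import analyze_scene


def pop_frame(pp):
    return pd.DataFrame({"distance_um": pp.grid_um, "mean": pp.mean,
                         "sem": pp.sem, "n": pp.n})


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--populations", type=Path, default=Path("results/populations"))
    ap.add_argument("--out", type=Path, default=Path("results/profiles"))
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for name in ("wt_like", "dtag_like"):
        channels, px = sg.read_scene(args.populations / f"{name}.tif")
        truth = pd.read_csv(args.populations / f"{name}_truth.csv")
        res = analyze_scene(channels, px)
        s = res["summary"]
        planted = 100 * truth.miscompartmentalized.mean()
        print(f"{name}: {s['n_cells']} cells segmented; "
              f"mis-compartmentalized {s['miscompartmentalized_pct']:.1f}% "
              f"(planted {planted:.1f}%)")
        rows = [{"cell_id": c.cell_id, "category": c.category, "f_fs": c.f_fs,
                 "rho": c.rho, "septum_snorm": c.septum_snorm,
                 "length_um": c.length_um} for c in res["calls"]]
        pd.DataFrame(rows).to_csv(args.out / f"{name}_calls.csv", index=False)
        if res["population_profile"] is not None:
            pop_frame(res["population_profile"]).to_csv(
                args.out / f"{name}_population_profile.csv", index=False)

    # random-pole control on the undivided polar-cap population
    channels, px = sg.read_scene(args.populations / "polar_cap_undivided.tif")
    res = analyze_scene(channels, px)
    profs = [p for p in res["profiles"] if p.usable]
    pop, _ = random_pole_profiles(profs, n_poles=20, seed=args.seed, min_n=3)
    pop_frame(pop).to_csv(args.out / "polar_cap_random_pole_profile.csv", index=False)
    near = np.nanmean(pop.mean[pop.grid_um <= 0.3])
    far = np.nanmean(pop.mean[(pop.grid_um >= 2.0) & (pop.grid_um <= 3.0)])
    print(f"polar_cap random-pole profile: mean ratio {near:.2f} at 0-0.3 um "
          f"vs {far:.2f} at 2-3 um (pole enrichment recovered: {near > far})")


if __name__ == "__main__":
    main()
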