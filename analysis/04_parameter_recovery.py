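"""Monte-Carlo check that the pipeline recovers injected kinetics.

Simulates seeded replicates of the default study with the cohort-mean
kinetics at 2% noise, runs the ROI analysis on the ground-truth masks, and
reports per-compartment recovery: peak time within one 30-min schedule
step and relative increase within 10% relative error. Writes the per-
replicate results to results/recovery.csv.

Run: python analysis/04_parameter_recovery.py [--replicates 10]
"""

import argparse
from pathlib import Path

import pandas as pd

from lipidmsot import (
    KineticParams,
    build_forearm_phantom,
    extract_timecourse,
    peak_time,
    relative_increase,
    simulate_study,
)

KINETICS = {
    "vein": KineticParams(amplitude=0.839, peak_time=187.5),
    "artery": KineticParams(amplitude=0.634, peak_time=232.5),
    "muscle": KineticParams(amplitude=1.208, peak_time=180.0),
    "fat": KineticParams(amplitude=0.328, peak_time=217.5),
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--replicates", type=int, default=10)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/recovery.csv"))
    args = parser.parse_args()

    rows = []
    for rep in range(args.replicates):
        seed = args.seed + rep
        geometry = build_forearm_phantom(seed=seed)
        study = simulate_study(geometry, KINETICS, noise_frac=0.02, seed=seed)
        for name, params in KINETICS.items():
            course = extract_timecourse(study, study.ground_truth_masks[name], 930.0)
            pt, ri = peak_time(course), relative_increase(course)
            rows.append(dict(
                seed=seed, compartment=name,
                true_peak_min=params.peak_time, peak_time_min=pt,
                true_increase_pct=100 * params.amplitude, relative_increase_pct=ri,
                peak_ok=abs(pt - params.peak_time) <= 30.0,
                increase_ok=abs(ri - 100 * params.amplitude)
                / (100 * params.amplitude) <= 0.10,
            ))
    results = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(args.out, index=False)
    rates = results.groupby("compartment")[["peak_ok", "increase_ok"]].mean()
    print(rates.to_string())
    print(f"{len(results)} compartment-replicates -> {args.out}")


if __name__ == "__main__":
    main()
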