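#!/usr/bin/env python
"""Simulate the four-arm imaging cohort and export example ROIs.

Generates the genotype x treatment design (WT / R6/2, vehicle / ACVR2B/Fc)
with hypertrophy in the treated arms, writes one example two-channel ROI
per arm (TIFFs plus ground-truth CSVs) under scratch/cohort_images/, and a
per-arm ground-truth summary under results/.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from myoagg.pipeline import DEMO_SIM, roi_seed
from myoagg.simgen import simulate_roi, write_roi

ARMS = [
    ("WT", "vehicle", 1.0),
    ("WT", "ACVR2B/Fc", 1.3),
    ("R6/2", "vehicle", 1.0),
    ("R6/2", "ACVR2B/Fc", 1.3),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--rois-per-arm", type=int, default=6)
    args = parser.parse_args()

    img_dir = Path("scratch/cohort_images")
    out_dir = Path("results")
    out_dir.mkdir(exist_ok=True)

    rows = []
    for gi, (geno, treat, h) in enumerate(ARMS):
        sim = replace(DEMO_SIM, hypertrophy_factor=h)
        for r in range(args.rois_per_arm):
            cfg = replace(sim, seed=roi_seed(args.seed, gi, 0, r))
            dapi, s830, truth = simulate_roi(cfg)
            if r == 0:
                stem = f"{geno.replace('/', '')}_{treat.replace('/', '')}"
                write_roi(img_dir, dapi, s830, truth, cfg, stem=stem)
            rows.append(
                {
                    "genotype": geno,
                    "treatment": treat,
                    "hypertrophy": h,
                    "roi": r,
                    "n_nuclei": len(truth.nuclei),
                    "n_inclusions": len(truth.inclusions),
                    "true_pct_signal_nuclear": truth.true_pct_signal_nuclear,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "cohort_ground_truth.csv", index=False)
    summary = table.groupby(["genotype", "treatment"], sort=False).agg(
        nuclei=("n_nuclei", "mean"), inclusions=("n_inclusions", "mean")
    )
    print("Simulated cohort (ground-truth means per ROI):")
    print(summary.round(1).to_string())
    print(
        f"\nTreated arms carry hypertrophy x{ARMS[1][2]}: nuclei per ROI drop by "
        f"~{100 * (1 - 1 / ARMS[1][2] ** 2):.0f}% while the per-nucleus inclusion "
        "process is unchanged."
    )
    print(f"Example ROIs written to {img_dir}/, table to {out_dir}/cohort_ground_truth.csv")


if __name__ == "__main__":
    main()
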