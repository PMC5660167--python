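#!/usr/bin/env python
"""Reconcile per-mass and per-nucleus aggregate readouts under hypertrophy.

Runs the golden-path demo: a vehicle arm and a hypertrophic treated arm
with an identical per-nucleus inclusion process are simulated, quantified,
and fed into the per-mass signal model.  The per-mass (ELISA-like) ratio
falls with nuclear density while the per-nucleus image ratio stays at 1,
so the verdict is "dilution", not "disease-modifying".  Reports are
written to results/reconciliation.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from myoagg.pipeline import run_figure5_demo


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-seeds", type=int, default=5)
    args = parser.parse_args()

    reports = [run_figure5_demo(seed=args.seed + k) for k in range(args.n_seeds)]
    table = pd.DataFrame(reports)
    out = Path("results")
    out.mkdir(exist_ok=True)
    table.to_csv(out / "reconciliation.csv", index=False)

    cols = ["seed", "nuclei_ratio", "size_ratio", "elisa_ratio", "image_ratio", "verdict"]
    print("Hypertrophy (x1.3) with fixed per-nucleus aggregation:")
    print(table[cols].round(3).to_string(index=False))
    frac = (table["verdict"] == "dilution").mean()
    print(
        f"\nDilution verdict in {frac:.0%} of {args.n_seeds} replicate cohorts: "
        "the per-mass signal drop is explained by nuclear thinning, not by "
        "reduced per-nucleus aggregation."
    )
    print(f"Table written to {out}/reconciliation.csv")


if __name__ == "__main__":
    main()
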