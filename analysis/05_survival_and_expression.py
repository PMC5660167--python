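#!/usr/bin/env python
"""Survival analysis and expression-data utilities on synthetic cohorts.

Simulates an end-stage survival experiment in which treatment lowers the
hazard, fits Kaplan-Meier curves and the Mantel-Cox log-rank test; then
demonstrates the RNA-seq gene-retention filter (count >= 2 in >= 10
samples) and geometric-mean qPCR normalization on synthetic data.  Tables
go under results/survival/ and results/expression/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from myoagg.simgen import simulate_counts, simulate_survival
from myoagg.stats import gene_filter, km_logrank, qpcr_fold_change


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    surv_dir = Path("results/survival")
    expr_dir = Path("results/expression")
    surv_dir.mkdir(parents=True, exist_ok=True)
    expr_dir.mkdir(parents=True, exist_ok=True)

    # end-stage delayed by treatment: hazard ratio 3, vehicle median ~60 d
    cohort = simulate_survival(
        17, {"vehicle": 1 / 90.0, "ACVR2B/Fc": 1 / 270.0}, censor_time=160.0,
        seed=args.seed,
    )
    cohort.to_csv(surv_dir / "cohort.csv", index=False)
    res = km_logrank(cohort)
    pd.concat(
        [df.assign(group=g) for g, df in res.curves.items()], ignore_index=True
    ).to_csv(surv_dir / "km_curves.csv", index=False)
    print(
        f"End-stage survival: log-rank chi-square {res.chi_square:.3f}, "
        f"p = {res.p:.4f} (n = 17/group)"
    )

    counts, expressed = simulate_counts(2000, 79, 0.6, seed=args.seed + 1)
    retained = gene_filter(counts, min_count=2, min_samples=10)
    pd.Series(retained, name="gene").to_csv(expr_dir / "retained_genes.csv", index=False)
    print(
        f"Gene filter: retained {len(retained)}/2000 genes "
        f"({len(set(retained) ^ set(expressed))} mismatches vs simulated truth)"
    )

    # qPCR: target doubled in one group, housekeeping genes stable
    rng = np.random.default_rng(args.seed + 2)
    groups = pd.Series(["WT"] * 8 + ["R6/2"] * 8)
    target = pd.Series(np.r_[rng.lognormal(3.0, 0.1, 8), rng.lognormal(3.0 + np.log(2), 0.1, 8)])
    hk = pd.DataFrame(
        {k: rng.lognormal(m, 0.05, 16) for k, m in (("Atp5b", 4.0), ("Actb", 5.0), ("Sdha", 3.5))}
    )
    fc = qpcr_fold_change(target, hk, groups, reference="WT")
    fc.rename("fold_change").to_csv(expr_dir / "qpcr_fold_change.csv")
    print(f"qPCR fold change vs WT (true 2.0): {fc['R6/2']:.2f}")
    print(f"Tables written to {surv_dir}/ and {expr_dir}/")


if __name__ == "__main__":
    main()
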