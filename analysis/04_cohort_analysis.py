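#!/usr/bin/env python
"""Longitudinal cohort statistics on a simulated transplant cohort.

One synthetic cohort (20 patients, 55% with allograft injury) is analyzed
the way the serial-sampling study design prescribes: paired pre-transplant
vs post-reperfusion Wilcoxon tests with fold changes, Spearman correlation
of hepatocyte Geq/mL with AST/ALT at POD0, and Mann-Whitney contrasts of
combined POD7/POD30 liver-epithelial signal between outcome arms, with
Benjamini-Hochberg q-values over the contrast family. A second pass repeats
the injury contrast across many seeds to report how often it is significant.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cfmeth.experiments import cohort_significance_experiment
from cfmeth.simulate import CohortSimConfig, simulate_cohort
from cfmeth.stats import (
    bh_adjust,
    enzyme_correlation,
    injury_contrast,
    pre_post_contrast,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--power-seeds", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = simulate_cohort(CohortSimConfig(seed=args.seed))
    table.to_csv(args.out / "cohort_example.csv", index=False)

    rows = []
    for ct in ("hepatocyte", "biliary"):
        res, med_fc = pre_post_contrast(table, ct)
        rows.append({"contrast": "PRE vs POD0 (Wilcoxon)", "cell_type": ct,
                     "statistic": res.statistic, "p": res.p_value, "n": res.n,
                     "median_fold_change": med_fc})
        res = injury_contrast(table, ct)
        rows.append({"contrast": "injury vs no-injury POD7/30 (Mann-Whitney)",
                     "cell_type": ct, "statistic": res.statistic, "p": res.p_value,
                     "n": res.n, "median_fold_change": np.nan})
    for enzyme in ("AST", "ALT"):
        res = enzyme_correlation(table, "hepatocyte", enzyme, "POD0")
        rows.append({"contrast": f"Spearman {enzyme} ~ hepatocyte Geq/mL @POD0",
                     "cell_type": "hepatocyte", "statistic": res.statistic,
                     "p": res.p_value, "n": res.n, "median_fold_change": np.nan})
    stats = pd.DataFrame(rows)
    stats["q"] = bh_adjust(stats["p"].to_numpy())
    stats.to_csv(args.out / "cohort_stats.tsv", sep="\t", index=False)
    with pd.option_context("display.width", 120):
        print(stats.round(4).to_string(index=False))

    print(f"\nrepeating the hepatocyte injury contrast over {args.power_seeds} seeds ...")
    power = cohort_significance_experiment(n_seeds=args.power_seeds, base_seed=args.seed * 1000)
    print(f"significant (p < 0.05) in {power.n_significant}/{power.n_seeds} cohorts "
          f"({power.fraction_significant:.0%})")
    pd.DataFrame({"p_value": power.p_values}).to_csv(
        args.out / "cohort_power.tsv", sep="\t", index=False
    )
    print(f"tables -> {args.out}/cohort_stats.tsv, cohort_power.tsv, cohort_example.csv")


if __name__ == "__main__":
    main()
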