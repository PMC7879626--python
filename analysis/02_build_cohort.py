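#!/usr/bin/env python
"""Build the gold-standard case/control cohort from the training period.

Screens possible T1D cases by the five clinical criteria (confirmed
diagnosis; insulin + low CPR + ketoacidosis; positive autoantibody;
diabetologist referral; very low CPR), adjudicates them against latent
truth (error-free by default, as chart review is treated as the reference
standard), applies the pancreas-transplant and T2D exclusions, and samples
controls from never-reviewed patients at 233 controls per case.

Writes cohort.csv to the run directory and a summary under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from phenoval.cohort import CohortConfig, build_cohort, write_cohort
from phenoval.data_model import read_dataset
from phenoval.simulate import read_truth


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--ratio", type=float, default=233.0)
    ap.add_argument("--run-dir", type=Path, default=Path("scratch/run"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    train = read_dataset(args.run_dir / "data" / "train", period="training")
    truth = read_truth(args.run_dir / "data" / "truth.csv")
    cohort = build_cohort(
        train, truth=truth, config=CohortConfig(control_ratio=args.ratio),
        seed=args.seed,
    )
    write_cohort(cohort, args.run_dir / "cohort.csv")

    summary = (
        cohort.groupby(["status", "exclusion_reason"], dropna=False)
        .size()
        .rename("n")
        .reset_index()
    )
    crit = (
        cohort.loc[cohort["status"] == "case", "matched_criteria"]
        .str.split("|")
        .explode()
        .value_counts()
        .rename("n_cases_matching")
        .rename_axis("criterion")
        .reset_index()
    )
    args.results.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.results / "02_cohort_summary.csv", index=False)
    crit.to_csv(args.results / "02_criteria_counts.csv", index=False)
    print(summary.to_string(index=False))
    print()
    print(crit.to_string(index=False))


if __name__ == "__main__":
    main()
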