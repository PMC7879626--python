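#!/usr/bin/env python
"""Train the gradient-boosted case-probability model on the cohort.

Builds the binary feature matrix (3-digit confirmed/suspected diagnoses,
generic-name medications, procedures, plus age and sex), removes the
leakage features used to construct the gold standard, screens to the top
500 features by relative risk, trains LightGBM and reports the ten-fold
cross-validated AUC and the top-10 gain importances.
"""

import argparse
from pathlib import Path

import pandas as pd

from phenoval.cohort import read_cohort
from phenoval.data_model import StudyDataset, read_dataset
from phenoval.features import build_features, screen_features
from phenoval.model import train


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--top-k", type=int, default=500)
    ap.add_argument("--run-dir", type=Path, default=Path("scratch/run"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    ds = read_dataset(args.run_dir / "data" / "train", period="training")
    cohort = read_cohort(args.run_dir / "cohort.csv")
    labeled = cohort[cohort["status"].isin(("case", "control"))]
    sub = StudyDataset(
        patients=ds.patients[ds.patients["patient_id"].isin(labeled["patient_id"])]
        .reset_index(drop=True),
        events=ds.events[ds.events["patient_id"].isin(labeled["patient_id"])]
        .reset_index(drop=True),
        labs=ds.labs,
        flags=ds.flags,
        period="training",
    )
    fm = build_features(sub)
    labels = (labeled.set_index("patient_id")["status"] == "case").astype(int)
    fm = screen_features(fm, labels, k=args.top_k)
    print(f"feature matrix: {fm.matrix.shape[0]} patients × {fm.matrix.shape[1]} columns")

    bundle = train(fm, labels, seed=args.seed)
    bundle.save(args.run_dir / "model.json")

    args.results.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"fold": range(1, len(bundle.cv_auc) + 1), "auc": bundle.cv_auc}
    ).to_csv(args.results / "03_cv_auc.csv", index=False)
    top10 = bundle.importance().head(10)
    top10.to_csv(args.results / "03_importance_top10.tsv", sep="\t", index=False)
    print(f"mean 10-fold CV AUC: {bundle.mean_cv_auc:.3f}")
    print(top10.to_string(index=False))


if __name__ == "__main__":
    main()
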