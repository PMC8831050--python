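#!/usr/bin/env python
"""Optional helper: run the pipeline on the UCI Parkinson's
Telemonitoring export (parkinsons_updrs.data, downloaded separately).

Maps the UCI column names onto the package schema and runs the full
experiment (EM k = 8, 10, 12, 13 ensembles fused by HGPA, cluster-wise
tuned SVR ensembles, subject-grouped holdout).  Not part of the test
surface — results depend on the external file.

Usage:  python scripts/run_uci.py parkinsons_updrs.data [--grid fast|full]
"""

from __future__ import annotations

import argparse

import pandas as pd

UCI_RENAME = {
    "subject#": "subject_id",
    "motor_UPDRS": "motor_updrs",
    "total_UPDRS": "total_updrs",
}
UCI_FEATURES = (
    "Jitter(%)", "Jitter(Abs)", "Jitter:RAP", "Jitter:PPQ5", "Jitter:DDP",
    "Shimmer", "Shimmer(dB)", "Shimmer:APQ3", "Shimmer:APQ5", "Shimmer:APQ11",
    "Shimmer:DDA", "NHR", "HNR", "RPDE", "DFA", "PPE",
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("csv", help="path to parkinsons_updrs.data")
    parser.add_argument("--grid", default="fast", choices=["fast", "full"])
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    from updrs.dataio import ColumnSchema, load_table, save_table
    from updrs.evaluate import ExperimentConfig, run_experiment
    from updrs.regress import FitConfig

    frame = pd.read_csv(args.csv).rename(columns=UCI_RENAME)
    tmp = "uci_renamed.csv"
    frame.to_csv(tmp, index=False)
    schema = ColumnSchema(subject_id="subject_id", features=UCI_FEATURES)
    table = load_table(tmp, schema)
    print(f"loaded {table.n_rows} recordings from "
          f"{len(set(table.subject_id))} subjects")

    cfg = ExperimentConfig(
        em_k=(8, 10, 12, 13), methods=("voting", "cspa", "hgpa"),
        fit=FitConfig(grid=args.grid, seed=args.seed),
        include_baselines=True, seed=args.seed,
    )
    result = run_experiment(cfg, table=table)
    print(result.report.to_string(index=False))
    result.report.to_csv("uci_report.csv", index=False)
    print("report -> uci_report.csv")


if __name__ == "__main__":
    main()
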