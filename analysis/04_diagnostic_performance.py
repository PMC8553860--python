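#!/usr/bin/env python
"""Diagnostic performance of every method against histology.

Builds the full validation table — Spearman r_s, and Az / SE / SP / ACC per
method, condition and diagnostic level (>=E1, >=D1, >=D2), with DeLong SEs
for Az, cluster-adjusted SEs for SE/SP and significance letter groups per
row — for the four algorithms (both conditions) and the in vivo visual
ICDAS examination (>=E1 and >=D2 only).  Writes results/summary.csv and the
formatted text table results/diagnostic_table.txt.
"""

import argparse
from pathlib import Path

from cariescan.cohort import read_cohort
from cariescan.calibration import load_cutoff_sets
from cariescan.pipeline import diagnostic_summary, format_report
from cariescan.scoring import Alg4Model, score_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--bootstrap-reps", type=int, default=2000)
    args = parser.parse_args()

    cohort = read_cohort(RESULTS / "cohorts" / "validation_cohort.csv")
    cutoff_sets = load_cutoff_sets(RESULTS / "cutoffs.json")
    model = Alg4Model.from_json(RESULTS / "alg4_model.json")
    scores = score_cohort(cohort, alg4_model=model, cutoff_sets=cutoff_sets)
    summary = diagnostic_summary(
        cohort, scores, bootstrap_reps=args.bootstrap_reps, seed=args.seed
    )
    summary.to_csv(RESULTS / "summary.csv", index=False, na_rep="NA")
    report = format_report(summary)
    (RESULTS / "diagnostic_table.txt").write_text(report)
    print(report)
    print(f"wrote {RESULTS / 'summary.csv'} and {RESULTS / 'diagnostic_table.txt'}")


if __name__ == "__main__":
    main()
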