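#!/usr/bin/env python
"""Calibrate the four algorithms' ordinal cut-offs on the calibration cohort.

Fits the ALG4 logistic model on the calibration cohort's in vitro signals,
computes every algorithm's raw severity scores, and derives the Youden-optimal
cut-off per diagnostic level (>=E1, >=D1 and, for ALG3/ALG4, >=D2), flagging
each as reliable when SE + SP > 1.7 at the optimum.  Writes
results/cutoffs.json and results/alg4_model.json.
"""

from pathlib import Path

from cariescan.calibration import calibrate_from_scores, save_cutoff_sets
from cariescan.cohort import read_cohort
from cariescan.histology import ALGORITHMS
from cariescan.scoring import fit_alg4, score_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohorts" / "calibration_cohort.csv")
    model = fit_alg4(cohort)
    model.to_json(RESULTS / "alg4_model.json")
    scores = score_cohort(cohort, alg4_model=model)
    cutoff_sets = {alg: calibrate_from_scores(scores, alg) for alg in ALGORITHMS}
    save_cutoff_sets(cutoff_sets, RESULTS / "cutoffs.json")
    for alg, cs in cutoff_sets.items():
        for entry in cs.entries:
            print(
                f"{alg} >= {entry.level.name}: threshold {entry.threshold:+.4f} "
                f"(SE {entry.se_at_cutoff:.2f}, SP {entry.sp_at_cutoff:.2f}, "
                f"{'reliable' if entry.reliable else 'NOT reliable'})"
            )
    print(f"wrote {RESULTS / 'cutoffs.json'} and {RESULTS / 'alg4_model.json'}")


if __name__ == "__main__":
    main()
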