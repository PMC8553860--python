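#!/usr/bin/env python
"""Score the blind validation cohort with the previously calibrated cut-offs.

Applies all four algorithms to the validation cohort's paired in vivo /
in vitro signals, converts raw scores to ordinal caries scores with the
calibration-cohort cut-offs, and tallies "insufficient scan" sites per
algorithm and condition.  Writes results/scores_validation.csv.
"""

from pathlib import Path

from cariescan.calibration import load_cutoff_sets
from cariescan.cohort import read_cohort
from cariescan.scoring import Alg4Model, score_cohort, write_scores

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohorts" / "validation_cohort.csv")
    cutoff_sets = load_cutoff_sets(RESULTS / "cutoffs.json")
    model = Alg4Model.from_json(RESULTS / "alg4_model.json")
    scores = score_cohort(cohort, alg4_model=model, cutoff_sets=cutoff_sets)
    write_scores(scores, RESULTS / "scores_validation.csv")
    missing = (
        scores[scores.raw_score.isna()]
        .groupby(["algorithm", "condition"])
        .size()
    )
    print("insufficient sites per algorithm x condition:")
    print(missing.to_string() if len(missing) else "  none")
    print(f"wrote {RESULTS / 'scores_validation.csv'}")


if __name__ == "__main__":
    main()
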