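#!/usr/bin/env python
"""In vivo vs. in vitro reproducibility of the automated scores.

For each algorithm: the McNemar-Bowker symmetry test on the paired ordinal
scores, paired DeLong comparisons of the in vivo and in vitro Az at every
calibrated level, and McNemar's test on the binary >=E1 calls among truly
carious sites (where biofilm red fluorescence could bias the in vivo
condition).  Writes results/condition_agreement.csv.
"""

from pathlib import Path

from cariescan.calibration import load_cutoff_sets
from cariescan.cohort import read_cohort
from cariescan.pipeline import condition_agreement
from cariescan.scoring import Alg4Model, score_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(RESULTS / "cohorts" / "validation_cohort.csv")
    cutoff_sets = load_cutoff_sets(RESULTS / "cutoffs.json")
    model = Alg4Model.from_json(RESULTS / "alg4_model.json")
    scores = score_cohort(cohort, alg4_model=model, cutoff_sets=cutoff_sets)
    agreement = condition_agreement(scores)
    agreement.to_csv(RESULTS / "condition_agreement.csv", index=False, na_rep="NA")

    bowker = agreement[agreement.comparison == "bowker_ordinal"]
    n_sig = int((bowker.p <= 0.05).sum())
    print(bowker[["algorithm", "statistic", "df", "p", "n"]].to_string(index=False))
    print(
        f"{n_sig} of {len(bowker)} algorithms show a significant in vivo/in vitro "
        "asymmetry of ordinal scores at alpha = 0.05"
    )
    print(f"wrote {RESULTS / 'condition_agreement.csv'}")


if __name__ == "__main__":
    main()
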