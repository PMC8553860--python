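#!/usr/bin/env python
"""Generate the study-replica cohorts.

Draws the calibration cohort (the "prior study" sample on which cut-offs are
defined) and an independent blind validation cohort — each 53 teeth carrying
118 occlusal examination sites with histological composition 17 sound / 79
enamel / 8 outer-dentin / 14 middle-inner-dentin — and writes both cohort
CSVs under results/cohorts/.
"""

import argparse
from collections import Counter
from pathlib import Path

from cariescan.cohort import cohort_sites, generate_cohort, write_cohort
from cariescan.pipeline import study_run_config

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cal_cfg, val_cfg = study_run_config(seed=args.seed).resolved_cohort_configs()
    out = RESULTS / "cohorts"
    out.mkdir(parents=True, exist_ok=True)
    for name, cfg in (("calibration", cal_cfg), ("validation", val_cfg)):
        cohort = generate_cohort(cfg)
        sites = cohort_sites(cohort)
        counts = Counter(s.histology_class.name for s in sites)
        write_cohort(cohort, out / f"{name}_cohort.csv")
        print(
            f"{name}: {len(cohort)} teeth, {len(sites)} sites, "
            f"composition E0={counts['E0']} E1/E2={counts['E1'] + counts['E2']} "
            f"D1={counts['D1']} >=D2={counts['D2'] + counts['D3']}"
        )
    print(f"wrote cohort CSVs to {out}")


if __name__ == "__main__":
    main()
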