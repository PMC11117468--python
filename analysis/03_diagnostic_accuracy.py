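#!/usr/bin/env python
"""Stratified diagnostic accuracy and ROC of the rule on the simulated cohort.

Builds the 2x2 table of rule call vs biopsy-proven cast nephropathy overall
and per involved-LC type, reports sensitivity/specificity/PPV/NPV with exact
binomial CIs, and exports ROC coordinates of the raw quotient.  Writes
results/accuracy.json and results/roc_<stratum>.csv.
"""

import argparse
import csv
import json
from pathlib import Path

from castquotient import read_cohort, run_analysis

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=RESULTS / "synthetic_cohort.csv")
    args = parser.parse_args()

    report = run_analysis(read_cohort(args.cohort))
    payload = report.to_dict()

    RESULTS.mkdir(parents=True, exist_ok=True)
    (RESULTS / "accuracy.json").write_text(
        json.dumps({"accuracy": payload["accuracy"]}, indent=2, sort_keys=True) + "\n"
    )
    for name, curve in report.accuracy.rocs.items():
        with open(RESULTS / f"roc_{name}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "tpr", "fpr"])
            writer.writerows(curve.operating_points())

    for name, acc in report.accuracy.reports.items():
        t = acc.table
        print(
            f"{name:<7} tp={t.tp:<3} fp={t.fp:<3} fn={t.fn:<3} tn={t.tn:<3} "
            f"sens={acc.sensitivity.value:.3f} spec={acc.specificity.value:.3f} "
            f"ppv={acc.ppv.value:.3f} npv={acc.npv.value:.3f} "
            f"auc={report.accuracy.rocs[name].auc:.3f}"
        )
    print(f"full report in {RESULTS / 'accuracy.json'}; ROC coordinates in roc_*.csv")


if __name__ == "__main__":
    main()
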