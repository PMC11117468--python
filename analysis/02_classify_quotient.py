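#!/usr/bin/env python
"""Apply the LC-type-specific quotient rule to the simulated cohort.

Reads results/synthetic_cohort.csv, computes each patient's urine-LC/eGFR
quotient and rule call at the published cut points (lambda: Q > 2; kappa:
Q > 5, or 1 < Q <= 5 with proteinuria < 8 g/24 h), and writes the per-patient
predictions to results/predictions.csv.
"""

import argparse
import csv
from pathlib import Path

from castquotient import apply_rule, read_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=RESULTS / "synthetic_cohort.csv")
    parser.add_argument("--out", type=Path, default=RESULTS / "predictions.csv")
    args = parser.parse_args()

    cohort = read_cohort(args.cohort)
    application = apply_rule(cohort)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "quotient", "positive", "branch"])
        for pid, pred in application.predictions.items():
            writer.writerow([pid, repr(pred.quotient), pred.positive, pred.branch.value])

    n_pos = sum(p.positive for p in application.predictions.values())
    print(f"classified {len(application.predictions)} patients: "
          f"{n_pos} rule-positive, {len(application.predictions) - n_pos} rule-negative")
    for pid, reason in application.exclusions.items():
        print(f"excluded {pid}: {reason}")
    print(f"predictions written to {args.out}")


if __name__ == "__main__":
    main()
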