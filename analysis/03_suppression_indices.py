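#!/usr/bin/env python
"""Summarize the suppression indices and place each subject on the
normative percentile table.

Reads ``results/subject_results.csv`` (from 02), prints the cohort means of
the left, right and bilateral suppression indices, checks the analysis
pipeline against the generator's ground truth where available, and writes
``results/si_placement.csv`` with each subject's normative percentile band.
"""

import argparse
from pathlib import Path

import pandas as pd

from qvor.suppression import load_normative_table, percentile_placement

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path,
                        default=ROOT / "results" / "subject_results.csv")
    parser.add_argument("--truth", type=Path,
                        default=ROOT / "results" / "cohort" / "ground_truth.csv")
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "si_placement.csv")
    args = parser.parse_args()

    results = pd.read_csv(args.results)
    for col, label in (("si_right", "right SI"), ("si_left", "left SI"),
                       ("si_bilateral", "bilateral SI")):
        print(f"mean {label}: {results[col].mean():.3f} "
              f"(sd {results[col].std(ddof=1):.3f})")

    if args.truth.exists():
        truth = pd.read_csv(args.truth)
        merged = results.merge(truth[["subject_id", "true_si_bilateral"]],
                               on="subject_id")
        err = (merged.si_bilateral - merged.true_si_bilateral).abs()
        print(f"bilateral SI recovery vs ground truth: "
              f"max |error| {err.max():.4f}, median {err.median():.4f}")

    table = load_normative_table()
    placement = pd.DataFrame(
        {
            "subject_id": results.subject_id,
            "si_bilateral": results.si_bilateral,
            "normative_band": [
                percentile_placement(v, "bilateral_si", table)
                for v in results.si_bilateral
            ],
        }
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    placement.to_csv(args.out, index=False)
    outside = placement.normative_band.isin(["below p5", "above p95"]).sum()
    print(f"{outside} of {len(placement)} subjects fall outside the normative "
          f"p5-p95 band -> {args.out}")


if __name__ == "__main__":
    main()
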