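"""Cohort summary of the four-subject pilot records.

Aggregates the transcribed per-subject (peak time, relative increase)
records into the per-compartment means and the peak-time variability by
compartment and by subject (sample SD, n-1). Writes summary.csv and
variability.csv to results/cohort/ and prints the Means rows.

Run: python analysis/03_cohort_summary.py
"""

import argparse
import tempfile
from importlib import resources
from pathlib import Path

import pandas as pd

from lipidmsot.pipeline import run_summarize


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--records", type=Path, default=None,
                        help="records CSV; defaults to the packaged pilot cohort")
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()

    if args.records is None:
        ref = resources.files("lipidmsot.data") / "pilot_cohort_records.csv"
        with resources.as_file(ref) as path:
            summary_path = run_summarize(path, args.out)
    else:
        summary_path = run_summarize(args.records, args.out)

    summary = pd.read_csv(summary_path)
    means = summary[summary["subject"] == "Means"]
    print(means.to_string(index=False))
    print((args.out / "variability.csv").read_text())


if __name__ == "__main__":
    main()
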