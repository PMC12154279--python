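#!/usr/bin/env python
"""Hemisphere and group statistics of the cohort metabolite ratios.

Runs, per metric: paired ipsi-vs-contra t-tests within each group, the
per-group mean +/- SE summaries with hemisphere relative differences, and
the assumption-gated (Shapiro-Wilk + Brown-Forsythe) naive-vs-injury
comparison of the per-subject relative differences.  Writes stats.json and
prints the headline findings.
"""

import argparse
from pathlib import Path

import pandas as pd

from hpcsi.io import save_json
from hpcsi.pipeline import cohort_statistics


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    wide = pd.read_csv(args.cohort / "ratios.csv")
    report = cohort_statistics(wide, alpha=args.alpha)
    save_json(report, args.cohort / "stats.json")

    for metric in ("lac_pyr", "bic_pyr", "bic_lac", "ala_pyr"):
        entry = report.get(metric)
        if not entry:
            continue
        print(f"\n{metric}:")
        for row in entry["summary"]:
            print(
                f"  {row['group']:>7}: ipsi {row['ipsi_mean']:.3f} +/- "
                f"{row['ipsi_se']:.3f}, contra {row['contra_mean']:.3f} +/- "
                f"{row['contra_se']:.3f}, rel diff {row['rel_diff_mean']:+.3f}"
            )
        for group in ("naive", "injury"):
            paired = entry.get(f"paired_{group}")
            if paired:
                print(f"  paired {group}: t = {paired['statistic']:.2f}, "
                      f"p = {paired['p_value']:.4f}")
        gr = entry.get("group_rel_diff")
        if gr:
            print(f"  group comparison ({gr['test']}): p = {gr['p_value']:.4f}")
    print(f"\nwrote {args.cohort / 'stats.json'}")


if __name__ == "__main__":
    main()
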