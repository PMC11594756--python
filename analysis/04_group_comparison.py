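"""Compare the groups statistically: per-DIV Kruskal-Wallis omnibus tests on
every activity parameter plus fold changes vs each group's DIV14 baseline.

Reads results/burst_statistics.csv (run 02 first), writes
results/fold_changes.csv and results/group_comparisons.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from meanet.stats import fold_change_report, group_comparison_table

SUMMARY = Path("results/burst_statistics.csv")


def main() -> int:
    if not SUMMARY.exists():
        print("no statistics table found; run analysis/02_burst_statistics.py first",
              file=sys.stderr)
        return 1
    df = pd.read_csv(SUMMARY, comment="#")

    folds = fold_change_report(df)
    folds.to_csv("results/fold_changes.csv", index=False, float_format="%.6g")
    comp = group_comparison_table(df, posthoc=True)
    comp.to_csv("results/group_comparisons.csv", index=False, float_format="%.6g")

    print(f"wrote results/fold_changes.csv ({len(folds)} rows) and "
          f"results/group_comparisons.csv ({len(comp)} rows)")
    final = comp[
        (comp["div"] == 21)
        & (comp["metric"] == "pct_spikes_in_bursts")
        & (comp["comparison"] == "omnibus")
    ]
    if not final.empty:
        h = final["statistic"].item()
        p = final["p"].item()
        print(f"\npct of spikes in bursts at the final DIV: "
              f"Kruskal-Wallis H = {h:.2f}, p = {p:.4g}")
        print("significant at p <= 0.05" if p <= 0.05 else "not significant")
    ab = folds[(folds["group"] == "Ab") & (folds["div"] == 21)]
    if not ab.empty:
        print(f"amyloid group fold change vs its DIV14 baseline "
              f"(pct spikes in bursts): {ab['fold_pct_spikes_in_bursts'].item():.2f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
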