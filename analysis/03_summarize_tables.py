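"""Narrative summary of the scenario-grid results.

Reads results/replicates.csv (written by 02_run_scenarios.py) and prints the
headline comparisons: how clonal replication (N_R) moves BLUP and GBLUP
accuracy, where genomic evaluation overtakes pedigree evaluation as marker
density grows, and how the paired gain advantage of GBLUP shrinks as clonal
replication is added.  Writes results/headline_comparisons.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> int:
    path = OUT / "replicates.csv"
    if not path.exists():
        print("run analysis/02_run_scenarios.py first", file=sys.stderr)
        return 1
    df = pd.read_csv(path)

    acc = df[df.statistic == "accuracy"]
    piv = acc.pivot_table(index=["family_size", "marker_density", "n_r"],
                          columns="method", values="value", aggfunc="mean")
    piv["ratio_pct"] = 100 * piv["GBLUP"] / piv["BLUP"]
    print("Mean accuracies and GBLUP/BLUP ratio:")
    print(piv.round(3).to_string())

    rows = []
    gain = df[df.statistic == "gain"]
    for (fam, dens, nr, ne), sub in gain.groupby(["family_size", "marker_density", "n_r", "ne"]):
        wide = sub.pivot(index="seed", columns="method", values="value")
        if {"BLUP", "GBLUP"} <= set(wide.columns):
            d = wide["GBLUP"] - wide["BLUP"]
            t, p = stats.ttest_rel(wide["GBLUP"], wide["BLUP"])
            rows.append(dict(family_size=fam, marker_density=dens, n_r=nr, ne=ne,
                             gain_blup=wide["BLUP"].mean(), gain_gblup=wide["GBLUP"].mean(),
                             diff=d.mean(), se=d.std(ddof=1) / np.sqrt(len(d)),
                             p=p, significant=p < 0.05))
    res = pd.DataFrame(rows)
    res.to_csv(OUT / "headline_comparisons.csv", index=False)

    print("\nPaired GBLUP - BLUP standardized-gain differences (* = p < 0.05):")
    show = res.assign(flag=np.where(res.significant, "*", ""))
    print(show[["family_size", "marker_density", "n_r", "ne", "diff", "se", "flag"]]
          .round(3).to_string(index=False))

    print("\nHow the GBLUP gain advantage moves with clonal replication (Ne = 5):")
    sub = res[res["ne"] == 5]
    print(sub.pivot_table(index=["family_size", "marker_density"], columns="n_r",
                          values="diff").round(3).to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
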