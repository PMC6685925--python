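#!/usr/bin/env python
"""Group-level statistics over the simulated cohort.

Reads scores.csv from 02 and reproduces the study's statistical battery on
the guilty groups: the item-type (probe vs. irrelevant) x group mixed ANOVA
with Greenhouse-Geisser correction, the item-category ANOVA on the
probe-irrelevant differences, within-subject Cohen's d per group, and the
design power of the 2x2 interaction.  Writes anova.csv and effect_sizes.csv.
"""

from pathlib import Path

import pandas as pd

from ctpcit import stats

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores = pd.read_csv(OUT / "scores.csv")
    guilty = scores[scores.guilty & scores.condition.isin(["probe", "irrelevant"])]

    # per subject x condition, categories merged (item-type analysis)
    merged = (guilty.groupby(["subject", "group", "condition"], as_index=False)
              .p300pp_uv.mean())
    aov_type = stats.mixed_anova(merged, "p300pp_uv", "condition",
                                 "subject", "group")
    aov_type.insert(0, "analysis", "item_type_x_group")

    # per subject x category probe-irrelevant differences
    diffs = stats.diff_scores(guilty, "p300pp_uv", cond_col="condition",
                              by=("subject", "group", "category"))
    aov_cat = stats.mixed_anova(diffs, "p300pp_uv_diff", "category",
                                "subject", "group")
    aov_cat.insert(0, "analysis", "item_category_x_group")
    anova = pd.concat([aov_type, aov_cat], ignore_index=True)
    anova.to_csv(OUT / "anova.csv", index=False)

    rows = []
    for (group, cat), d in diffs.groupby(["group", "category"]):
        rows.append({"group": group, "category": cat,
                     "mean_diff_uv": d.p300pp_uv_diff.mean(),
                     "d_within": stats.cohen_d_within(d.p300pp_uv_diff)})
    eff = pd.DataFrame(rows)
    eff.to_csv(OUT / "effect_sizes.csv", index=False)

    power = stats.power_mixed_interaction(stats.PowerSpec())
    print("mixed ANOVA results:")
    print(anova[["analysis", "effect", "F", "df1", "df2", "eps", "p_gg", "np2"]]
          .round(3).to_string(index=False))
    print("\nprobe-irrelevant differences and d_within:")
    print(eff.round(2).to_string(index=False))
    print(f"\ndesign power (f=.25, alpha=.05, N=35, rho=.5): {power:.2f}")
    print(f"wrote anova.csv and effect_sizes.csv to {OUT}/")


if __name__ == "__main__":
    main()
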