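#!/usr/bin/env python
"""Regression and hypothesis tests on the extracted feature tables.

Per-trial, per-muscle MNF regressions (normalized MNF vs interval, plus the
relative fatigue slope in %/s from the raw MNF), first-vs-last paired
t-tests for all ten measures, per-trial wobble-measure regressions, and
one-way ANOVAs comparing MNF slopes across muscles and activities.
Reads the tables written by 01_simulate_features.py.
"""

import argparse
from pathlib import Path

import pandas as pd

from hipfatigue.features import ACCEL_MEASURES, FeatureTable
from hipfatigue.pipeline import (
    first_last_tests,
    measure_trial_regressions,
    mnf_trial_regressions,
)
from hipfatigue.recordings import MUSCLE_SHORT, MUSCLES
from hipfatigue.stats import slope_anova


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.results_dir

    raw = FeatureTable.from_csv(out / "feature_table_raw.csv", normalized=False)
    norm = FeatureTable.from_csv(out / "feature_table.csv", normalized=True)

    mnf_regs = mnf_trial_regressions(raw, norm)
    mnf_regs.to_csv(out / "mnf_regressions.csv", index=False)
    mean_rel = mnf_regs["rel_slope_pct_per_s"].mean()
    frac_neg = (mnf_regs["slope"] < 0).mean()
    print(f"MNF regressions: {len(mnf_regs)} muscle-trials; "
          f"{100 * frac_neg:.0f}% negative slopes; "
          f"mean relative slope {mean_rel:+.3f} %/s")

    measures = [f"mnf_{MUSCLE_SHORT[m]}" for m in MUSCLES] + ACCEL_MEASURES
    fl = first_last_tests(norm, measures)
    fl.to_csv(out / "first_last_ttests.csv", index=False)
    sig = fl[fl["p"] < 0.05]["measure"].tolist()
    print(f"first-vs-last paired t-tests: {len(sig)}/{len(fl)} measures "
          f"significant at 0.05: {sig}")

    acc_regs = measure_trial_regressions(norm, ACCEL_MEASURES)
    acc_regs.to_csv(out / "accel_regressions.csv", index=False)
    auc = acc_regs[acc_regs["measure"] == "acc_auc"]
    print(f"acceleration AUC regressions: {100 * (auc['slope'] > 0).mean():.0f}% "
          f"positive slopes (growing knee wobble)")

    rows, pair_frames = [], []
    for grouping, key, frame in [("muscle", "muscle", mnf_regs),
                                 ("activity", "activity", mnf_regs)]:
        groups = {g: sub["slope"].to_numpy() for g, sub in frame.groupby(key)}
        res, pw = slope_anova(groups, pairwise=True)
        rows.append({"grouping": grouping, "F": res.statistic, "p": res.p, "df": res.df})
        pw.insert(0, "grouping", grouping)
        pair_frames.append(pw)
        print(f"MNF slope ANOVA by {grouping}: F = {res.statistic:.2f}, p = {res.p:.3g}")
    pd.DataFrame(rows).to_csv(out / "slope_anova.csv", index=False)
    pd.concat(pair_frames).to_csv(out / "slope_anova_pairwise.csv", index=False)
    print(f"wrote mnf_regressions.csv, first_last_ttests.csv, accel_regressions.csv, "
          f"slope_anova[_pairwise].csv -> {out}/")


if __name__ == "__main__":
    main()
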