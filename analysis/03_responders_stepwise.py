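#!/usr/bin/env python
"""Responder labelling, stepwise wobble detection, and predictive values.

A muscle-trial is a fatigue responder when its MNF regression slope is
negative with p < 0.05; a trial is a knee-wobble responder when stepwise
selection over the four wobble measures retains at least one term with
p < 0.05.  Wobble responders are then scored as predictors of any-muscle
fatigue (PPV/NPV), and per-trial multivariate R² (summed MNF on the four
wobble measures) is summarized by the number of fatigued muscles.
"""

import argparse
from pathlib import Path

import pandas as pd

from hipfatigue.features import FeatureTable
from hipfatigue.pipeline import (
    build_labels,
    group_r2_by_responder_count,
    stepwise_wobble,
    trial_multivariate_r2,
)
from hipfatigue.responder import predictive_values


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.results_dir

    raw = FeatureTable.from_csv(out / "feature_table_raw.csv", normalized=False)
    norm = FeatureTable.from_csv(out / "feature_table.csv", normalized=True)
    mnf_regs = pd.read_csv(out / "mnf_regressions.csv")

    stepwise = stepwise_wobble(norm)
    labels = build_labels(mnf_regs, stepwise)
    labels_df = pd.DataFrame(
        [{"trial_id": l.trial_id, "gmd_fatigue": l.gmd_fatigue,
          "gmx_fatigue": l.gmx_fatigue, "rf_fatigue": l.rf_fatigue,
          "any_fatigue": l.any_fatigue, "n_fatigued": l.n_fatigued,
          "wobble": l.wobble} for l in labels]
    )
    labels_df.to_csv(out / "responder_labels.csv", index=False)

    n = len(labels_df)
    print(f"fatigue responders of {n} trials: "
          f"GMD {int(labels_df['gmd_fatigue'].sum())}, "
          f"GMX {int(labels_df['gmx_fatigue'].sum())}, "
          f"RF {int(labels_df['rf_fatigue'].sum())}; "
          f"wobble responders {int(labels_df['wobble'].sum())}")

    rep = predictive_values(labels_df["wobble"].astype(bool),
                            labels_df["any_fatigue"].astype(bool))
    print(f"wobble -> any-fatigue: PPV {rep.ppv:.0f}% ({rep.tp}/{rep.tp + rep.fp}), "
          f"NPV {rep.npv:.0f}% ({rep.tn}/{rep.tn + rep.fn})")

    mv = trial_multivariate_r2(norm, raw)
    mv.to_csv(out / "multivariate_r2.csv", index=False)
    summary, anova, pw = group_r2_by_responder_count(
        mv.set_index("trial_id")["r2"], labels_df.set_index("trial_id")["n_fatigued"]
    )
    summary.to_csv(out / "r2_by_responder_count.csv", index=False)
    if pw is not None:
        pw.to_csv(out / "r2_by_responder_count_pairwise.csv", index=False)
    print("multivariate R² by number of fatigued muscles:")
    for _, row in summary.iterrows():
        print(f"  {int(row['n_responders'])} responders: n={int(row['n_trials'])}, "
              f"mean R²={row['mean_r2']:.2f}")
    if anova is not None:
        print(f"  ANOVA across groups: F = {anova.statistic:.2f}, p = {anova.p:.3g}")
    print(f"wrote responder_labels.csv, multivariate_r2.csv, "
          f"r2_by_responder_count[_pairwise].csv -> {out}/")


if __name__ == "__main__":
    main()
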