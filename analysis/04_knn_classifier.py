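#!/usr/bin/env python
"""Cost-sensitive KNN prediction of muscle fatigue from acceleration features.

All four wobble measures across all ten intervals (40 features per trial)
feed a 27-neighbor Chebyshev KNN with Kruskal-Wallis feature selection,
misclassification costs 1 (false negative) : 4 (false positive), and
stratified five-fold cross-validation.  Truth labels are the sEMG-derived
any-muscle fatigue flags from 03_responders_stepwise.py.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from hipfatigue.features import FeatureTable
from hipfatigue.pipeline import accel_feature_matrix
from hipfatigue.responder import KnnConfig, knn_predict_fatigue


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = args.results_dir

    norm = FeatureTable.from_csv(out / "feature_table.csv", normalized=True)
    labels = pd.read_csv(out / "responder_labels.csv").set_index("trial_id")

    X, trial_ids, _ = accel_feature_matrix(norm)
    y = labels.loc[trial_ids, "any_fatigue"].astype(bool).to_numpy()
    cfg = KnnConfig(seed=args.seed)
    rep = knn_predict_fatigue(X, y, cfg)

    pd.DataFrame({"trial_id": trial_ids, "predicted": rep.predictions,
                  "truth": y}).to_csv(out / "knn_predictions.csv", index=False)
    report = {"pooled": rep.pooled.to_dict(ndigits=1),
              "per_fold": [r.to_dict(ndigits=1) for r in rep.per_fold],
              "config": {"k": cfg.k, "metric": cfg.metric,
                         "n_features_selected": cfg.n_features_selected,
                         "cost_fn": cfg.cost_false_negative,
                         "cost_fp": cfg.cost_false_positive,
                         "n_folds": cfg.n_folds, "seed": cfg.seed}}
    (out / "knn_report.json").write_text(json.dumps(report, indent=2))

    p = rep.pooled
    print(f"KNN ({cfg.k}-NN, {cfg.metric}, costs {cfg.cost_false_negative:g}:"
          f"{cfg.cost_false_positive:g}, {cfg.n_folds}-fold):")
    print(f"  pooled confusion tp={p.tp} fp={p.fp} tn={p.tn} fn={p.fn}")
    print(f"  PPV {p.ppv:.0f}% ({p.tp}/{p.tp + p.fp}), "
          f"NPV {p.npv:.0f}% ({p.tn}/{p.tn + p.fn})")
    print(f"wrote knn_predictions.csv, knn_report.json -> {out}/")


if __name__ == "__main__":
    main()
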