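"""End-to-end orchestration: simulate -> preprocess -> features -> stats ->
responder labelling -> classification -> report.

A run is fully determined by its :class:`RunConfig` (serializable to YAML),
writes every intermediate table as CSV so each stage is independently
inspectable, and finishes with a machine-readable JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .features import (
    ACCEL_MEASURES,
    FeatureConfig,
    FeatureTable,
    build_feature_table,
    normalize,
)
from .recordings import MUSCLE_SHORT, MUSCLES
from .responder import (
    KnnConfig,
    ResponderLabels,
    knn_predict_fatigue,
    label_muscle_responders,
    label_wobble_responder,
    predictive_values,
)
from .stats import (
    StepwiseResult,
    TestResult,
    first_last_ttest,
    interval_regression,
    multivariate_r2,
    slope_anova,
    stepwise_fit,
)
from .synthetic import AccelSynthParams, CohortSpec, SemgSynthParams, cohort_truth, iter_cohort

logger = logging.getLogger("hipfatigue")

__all__ = [
    "RunConfig",
    "RunReport",
    "run",
    "mnf_trial_regressions",
    "measure_trial_regressions",
    "first_last_tests",
    "stepwise_wobble",
    "trial_multivariate_r2",
    "accel_feature_matrix",
    "group_r2_by_responder_count",
    "build_labels",
]

#: seconds per interval at the default 86 s / 10 intervals segmentation
SECONDS_PER_INTERVAL = 8.6


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    alpha: float = 0.05
    p_enter: float = 0.05
    p_remove: float = 0.10
    #: "measures_predict_time": stepwise selects wobble measures predicting time
    #: "time_predicts_measures": each measure regressed on time, min p across measures
    stepwise_orientation: str = "measures_predict_time"
    sum_mnf_normalized: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if isinstance(c.get("semg"), dict):
                c["semg"] = SemgSynthParams(**c["semg"])
            if isinstance(c.get("accel"), dict):
                c["accel"] = AccelSynthParams(**c["accel"])
            for key in ("activities", "fatigue_slope_range"):
                if key in c and isinstance(c[key], list):
                    c[key] = tuple(c[key])
            d["cohort"] = CohortSpec(**c)
        if "features" in d and isinstance(d["features"], dict):
            f = dict(d["features"])
            if isinstance(f.get("emg_band"), list):
                f["emg_band"] = tuple(f["emg_band"])
            d["features"] = FeatureConfig(**f)
        if "knn" in d and isinstance(d["knn"], dict):
            d["knn"] = KnnConfig(**d["knn"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def mnf_trial_regressions(
    raw_table: FeatureTable, norm_table: FeatureTable
) -> pd.DataFrame:
    """Per-trial, per-muscle MNF regressions.

    The responder-defining fit is normalized MNF against interval index; the
    relative fatigue slope in %/s comes from raw MNF against the interval
    midpoint time (slope / intercept * 100), directly comparable to published
    fatigue-slope magnitudes.
    """
    rows = []
    raw, norm = raw_table.data, norm_table.data
    for trial_id, g_norm in norm.groupby("trial_id", sort=False):
        g_raw = raw[raw["trial_id"] == trial_id]
        for muscle in MUSCLES:
            col = f"mnf_{MUSCLE_SHORT[muscle]}"
            reg = interval_regression(g_norm[col], g_norm["interval_index"])
            reg_raw = interval_regression(g_raw[col], g_raw["t_mid"])
            rel_slope = (
                100.0 * reg_raw.slope / reg_raw.intercept
                if reg_raw.intercept != 0
                else float("nan")
            )
            rows.append(
                {
                    "trial_id": trial_id,
                    "subject": g_norm["subject"].iloc[0],
                    "activity": g_norm["activity"].iloc[0],
                    "muscle": muscle,
                    "slope": reg.slope,
                    "slope_per_s": reg.slope / SECONDS_PER_INTERVAL,
                    "intercept": reg.intercept,
                    "p_slope": reg.p_slope,
                    "r2": reg.r2,
                    "n": reg.n,
                    "rel_slope_pct_per_s": rel_slope,
                }
            )
    return pd.DataFrame(rows)


def measure_trial_regressions(table: FeatureTable, measures: list[str]) -> pd.DataFrame:
    """Per-trial OLS of each measure against interval index."""
    rows = []
    for trial_id, g in table.data.groupby("trial_id", sort=False):
        for col in measures:
            try:
                reg = interval_regression(g[col], g["interval_index"])
            except ValueError:
                continue  # too few finite values (e.g. mostly-missing ZCR)
            rows.append(
                {
                    "trial_id": trial_id,
                    "subject": g["subject"].iloc[0],
                    "activity": g["activity"].iloc[0],
                    "measure": col,
                    "slope": reg.slope,
                    "p_slope": reg.p_slope,
                    "r2": reg.r2,
                    "n": reg.n,
                }
            )
    return pd.DataFrame(rows)


def first_last_tests(table: FeatureTable, measures: list[str]) -> pd.DataFrame:
    """Paired first-vs-last-interval t-tests across trials, per measure."""
    df = table.data
    n_int = int(df["interval_index"].max())
    first = df[df["interval_index"] == 1].set_index("trial_id")
    last = df[df["interval_index"] == n_int].set_index("trial_id")
    common = first.index.intersection(last.index)
    rows = []
    for col in measures:
        a = first.loc[common, col]
        b = last.loc[common, col]
        mask = a.notna() & b.notna()
        try:
            res = first_last_ttest(a[mask], b[mask])
        except ValueError as exc:
            logger.warning("first/last t-test skipped for %s: %s", col, exc)
            continue
        rows.append(
            {
                "measure": col,
                "t": res.statistic,
                "p": res.p,
                "df": res.df,
                "mean_first": float(a[mask].mean()),
                "mean_last": float(b[mask].mean()),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def stepwise_wobble(
    table: FeatureTable,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    orientation: str = "measures_predict_time",
) -> dict[str, Optional[StepwiseResult]]:
    """Per-trial stepwise selection of wobble measures carrying a time trend.

    Default orientation regresses interval index on the four wobble measures
    and selects terms; the mirror orientation regresses each measure on time
    and reports each measure's own slope p-value as its "term" p-value.
    """
    results: dict[str, Optional[StepwiseResult]] = {}
    for trial_id, g in table.data.groupby("trial_id", sort=False):
        if orientation == "measures_predict_time":
            X = g[ACCEL_MEASURES]
            y = g["interval_index"]
            try:
                results[trial_id] = stepwise_fit(X, y, p_enter=p_enter, p_remove=p_remove)
            except ValueError as exc:
                logger.warning("stepwise skipped for trial %s: %s", trial_id, exc)
                results[trial_id] = None
        elif orientation == "time_predicts_measures":
            term_p = {}
            for col in ACCEL_MEASURES:
                try:
                    reg = interval_regression(g[col], g["interval_index"])
                except ValueError:
                    continue
                if reg.p_slope < p_enter:
                    term_p[col] = reg.p_slope
            results[trial_id] = StepwiseResult(
                retained_terms=tuple(term_p),
                term_pvalues=term_p,
                overall_p=min(term_p.values()) if term_p else float("nan"),
            )
        else:
            raise ValueError(f"unknown stepwise orientation {orientation!r}")
    return results


def build_labels(
    mnf_regs: pd.DataFrame,
    stepwise: dict[str, Optional[StepwiseResult]],
    alpha: float = 0.05,
) -> list[ResponderLabels]:
    """Combine MNF regressions and stepwise results into per-trial labels."""
    from .stats import RegressionResult

    labels = []
    for trial_id, g in mnf_regs.groupby("trial_id", sort=False):
        regs = {}
        for muscle in MUSCLES:
            row = g[g["muscle"] == muscle]
            regs[muscle] = (
                RegressionResult(
                    slope=float(row["slope"].iloc[0]),
                    intercept=float(row["intercept"].iloc[0]),
                    p_slope=float(row["p_slope"].iloc[0]),
                    r2=float(row["r2"].iloc[0]),
                    n=int(row["n"].iloc[0]),
                )
                if len(row)
                else None
            )
        flags = label_muscle_responders(regs, alpha=alpha)
        labels.append(
            ResponderLabels(
                trial_id=trial_id,
                gmd_fatigue=flags["gluteus_medius"],
                gmx_fatigue=flags["gluteus_maximus"],
                rf_fatigue=flags["rectus_femoris"],
                wobble=label_wobble_responder(stepwise.get(trial_id), alpha=alpha),
            )
        )
    return labels


def trial_multivariate_r2(
    norm_table: FeatureTable, raw_table: FeatureTable, use_normalized: bool = True
) -> pd.DataFrame:
    """Per-trial OLS of the summed three-muscle MNF on the four wobble measures."""
    table = norm_table if use_normalized else raw_table
    mnf_cols = [f"mnf_{MUSCLE_SHORT[m]}" for m in MUSCLES]
    rows = []
    for trial_id, g in table.data.groupby("trial_id", sort=False):
        y = g[mnf_cols].sum(axis=1)
        try:
            res = multivariate_r2(g[ACCEL_MEASURES], y)
        except ValueError as exc:
            logger.warning("multivariate fit skipped for trial %s: %s", trial_id, exc)
            continue
        rows.append(
            {"trial_id": trial_id, "r2": res.r2, "p_overall": res.p_overall, "n": res.n}
        )
    return pd.DataFrame(rows)


def accel_feature_matrix(table: FeatureTable) -> tuple[np.ndarray, list[str], list[str]]:
    """Trials x (4 wobble measures x n_intervals) matrix for the classifier.

    Columns are ordered measure-major (``acc_max_i1 ... acc_zcr_i10``); NaNs
    (missing ZCR intervals) are left in place for fold-wise imputation.
    """
    wide = table.data.pivot_table(
        index="trial_id", columns="interval_index", values=ACCEL_MEASURES,
        dropna=False, sort=False,
    )
    cols = [
        (measure, i)
        for measure in ACCEL_MEASURES
        for i in sorted(table.data["interval_index"].unique())
    ]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    trial_order = list(table.data["trial_id"].drop_duplicates())
    wide = wide.reindex(trial_order)
    names = [f"{m}_i{i}" for m, i in cols]
    return wide.to_numpy(dtype=float), trial_order, names


def group_r2_by_responder_count(
    r2: pd.Series, counts: pd.Series
) -> tuple[pd.DataFrame, Optional[TestResult], Optional[pd.DataFrame]]:
    """Summarize multivariate R² partitioned by number of fatigued muscles (0-3).

    Returns (group summary, ANOVA result, pairwise comparisons); the latter two
    are None when fewer than two non-empty groups exist.
    """
    common = r2.index.intersection(counts.index)
    r2, counts = r2.loc[common], counts.loc[common]
    summary_rows = []
    groups = {}
    for k in range(len(MUSCLES) + 1):
        vals = r2[counts == k].dropna()
        summary_rows.append(
            {
                "n_responders": k,
                "n_trials": int(vals.size),
                "mean_r2": float(vals.mean()) if vals.size else float("nan"),
                "sem_r2": float(vals.sem()) if vals.size > 1 else float("nan"),
            }
        )
        if vals.size >= 2:
            groups[str(k)] = vals.to_numpy()
    summary = pd.DataFrame(summary_rows)
    if len(groups) < 2:
        return summary, None, None
    anova, pairwise = slope_anova(groups, pairwise=True)
    return summary, anova, pairwise


@dataclass
class RunReport:
    """Summary of one full pipeline run (details live in the written CSVs)."""

    n_trials: int
    n_feature_rows: int
    responder_counts: dict
    wobble_responders: int
    stepwise_report: dict
    knn_report: dict
    r2_by_responder_count: list[dict]
    dropped: list[str]
    paths: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def run(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute the full analysis and write all tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dropped: list[str] = []
    paths: dict[str, str] = {}

    # --- simulate + featurize (trials realized one at a time) ---------------
    truth = cohort_truth(config.cohort)
    feat_cfg = dataclasses.replace(config.features, normalize=False)
    raw_table = build_feature_table(iter_cohort(config.cohort, truth), feat_cfg)
    norm_table = normalize(raw_table, config.features.grouping)
    truth.to_csv(out / "cohort_truth.csv", index=False)
    raw_table.to_csv(out / "feature_table_raw.csv")
    norm_table.to_csv(out / "feature_table.csv")
    paths.update(
        cohort_truth=str(out / "cohort_truth.csv"),
        feature_table_raw=str(out / "feature_table_raw.csv"),
        feature_table=str(out / "feature_table.csv"),
    )

    # --- regressions & tests ------------------------------------------------
    mnf_regs = mnf_trial_regressions(raw_table, norm_table)
    mnf_regs.to_csv(out / "mnf_regressions.csv", index=False)
    paths["mnf_regressions"] = str(out / "mnf_regressions.csv")

    all_measures = [f"mnf_{MUSCLE_SHORT[m]}" for m in MUSCLES] + ACCEL_MEASURES
    fl = first_last_tests(norm_table, all_measures)
    fl.to_csv(out / "first_last_ttests.csv", index=False)
    paths["first_last_ttests"] = str(out / "first_last_ttests.csv")

    acc_regs = measure_trial_regressions(norm_table, ACCEL_MEASURES)
    acc_regs.to_csv(out / "accel_regressions.csv", index=False)
    paths["accel_regressions"] = str(out / "accel_regressions.csv")

    anova_rows = []
    pairwise_frames = []
    slope_groups = {
        "muscle": {m: mnf_regs.loc[mnf_regs["muscle"] == m, "slope"].to_numpy() for m in MUSCLES},
        "activity": {
            a: mnf_regs.loc[mnf_regs["activity"] == a, "slope"].to_numpy()
            for a in config.cohort.activities
        },
    }
    for grouping, groups in slope_groups.items():
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            dropped.append(f"slope ANOVA by {grouping}: fewer than 2 groups, skipped")
            continue
        try:
            res, pw = slope_anova(groups, pairwise=True)
        except ValueError as exc:
            dropped.append(f"slope ANOVA by {grouping}: {exc}")
            continue
        anova_rows.append({"grouping": grouping, "F": res.statistic, "p": res.p, "df": res.df})
        pw.insert(0, "grouping", grouping)
        pairwise_frames.append(pw)
    pd.DataFrame(anova_rows).to_csv(out / "slope_anova.csv", index=False)
    if pairwise_frames:
        pd.concat(pairwise_frames).to_csv(out / "slope_anova_pairwise.csv", index=False)
    paths["slope_anova"] = str(out / "slope_anova.csv")

    # --- responder labelling ------------------------------------------------
    stepwise = stepwise_wobble(
        norm_table, config.p_enter, config.p_remove, config.stepwise_orientation
    )
    labels = build_labels(mnf_regs, stepwise, alpha=config.alpha)
    labels_df = pd.DataFrame(
        [
            {
                "trial_id": lab.trial_id,
                "gmd_fatigue": lab.gmd_fatigue,
                "gmx_fatigue": lab.gmx_fatigue,
                "rf_fatigue": lab.rf_fatigue,
                "any_fatigue": lab.any_fatigue,
                "n_fatigued": lab.n_fatigued,
                "wobble": lab.wobble,
            }
            for lab in labels
        ]
    )
    labels_df.to_csv(out / "responder_labels.csv", index=False)
    paths["responder_labels"] = str(out / "responder_labels.csv")

    responder_counts = {
        "gluteus_medius": int(labels_df["gmd_fatigue"].fillna(False).sum()),
        "gluteus_maximus": int(labels_df["gmx_fatigue"].fillna(False).sum()),
        "rectus_femoris": int(labels_df["rf_fatigue"].fillna(False).sum()),
        "any": int(labels_df["any_fatigue"].fillna(False).sum()),
    }
    n_missing = int(labels_df["any_fatigue"].isna().sum() + labels_df["wobble"].isna().sum())
    if n_missing:
        dropped.append(f"{n_missing} trials with missing labels excluded from predictive values")

    # --- wobble responders as predictors of any-muscle fatigue --------------
    valid = labels_df.dropna(subset=["any_fatigue", "wobble"])
    stepwise_rep = predictive_values(
        valid["wobble"].astype(bool), valid["any_fatigue"].astype(bool)
    )

    # --- multivariate R² grouped by responder count --------------------------
    mv = trial_multivariate_r2(norm_table, raw_table, config.sum_mnf_normalized)
    mv.to_csv(out / "multivariate_r2.csv", index=False)
    paths["multivariate_r2"] = str(out / "multivariate_r2.csv")
    summary, anova, pw = group_r2_by_responder_count(
        mv.set_index("trial_id")["r2"], labels_df.set_index("trial_id")["n_fatigued"]
    )
    if anova is None:
        dropped.append("R² by responder count: fewer than 2 non-empty groups, ANOVA skipped")
    summary.to_csv(out / "r2_by_responder_count.csv", index=False)
    paths["r2_by_responder_count"] = str(out / "r2_by_responder_count.csv")

    # --- KNN classifier -------------------------------------------------------
    X, trial_ids, feat_names = accel_feature_matrix(norm_table)
    y = labels_df.set_index("trial_id").loc[trial_ids, "any_fatigue"].fillna(False).astype(bool)
    knn_dict: dict = {}
    try:
        knn = knn_predict_fatigue(X, y.to_numpy(), config.knn)
        pd.DataFrame(
            {"trial_id": trial_ids, "predicted": knn.predictions, "truth": y.to_numpy()}
        ).to_csv(out / "knn_predictions.csv", index=False)
        paths["knn_predictions"] = str(out / "knn_predictions.csv")
        knn_dict = {
            "pooled": knn.pooled.to_dict(ndigits=1),
            "per_fold": [r.to_dict(ndigits=1) for r in knn.per_fold],
        }
    except ValueError as exc:
        dropped.append(f"KNN classification skipped: {exc}")

    report = RunReport(
        n_trials=int(labels_df.shape[0]),
        n_feature_rows=int(norm_table.data.shape[0]),
        responder_counts=responder_counts,
        wobble_responders=int(valid["wobble"].astype(bool).sum()),
        stepwise_report=stepwise_rep.to_dict(ndigits=1),
        knn_report=knn_dict,
        r2_by_responder_count=summary.to_dict(orient="records"),
        dropped=dropped,
        paths=paths,
    )
    report.to_json(out / "report.json")
    return report
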