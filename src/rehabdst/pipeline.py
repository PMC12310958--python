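"""End-to-end orchestration: logs -> clean series -> tensors -> models -> report.

The stages follow the data-management method the package implements:

1. :func:`prepare_cohort` — automode removal, round averaging, mutuality
   filtering, missing-value filling, patient exclusions, shrinking of long
   series to the 64-point grid and time-related feature computation;
2. :func:`build_cohort_tensor` — per-fold normalization and assembly of the
   ``patients x 64 x 36`` tensor;
3. :func:`run_cross_validation` — shared patient-level folds, the two
   recurrent decision-support tools, the random-forest baselines, pooled
   per-session error metrics, OA/F1, MCID stratification, paired model
   comparisons and (optionally) permutation importances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, features, harmonize, ingest, models, normalize, tensors
from .schema import CLINICAL_SCALES, FeatureSchema, ROBOT_PARAMETERS, level_to_index
from .tensors import CohortTensor, LookbackDataset

logger = logging.getLogger(__name__)

TARGET_LENGTH_DEFAULT = 64


@dataclass
class PreparedCohort:
    """Clean per-patient series on the fixed time grid, pre-normalization."""

    patients: pd.DataFrame
    series: dict[str, pd.DataFrame]  # pid -> harmonized chronological sessions
    time_features: dict[str, pd.DataFrame]  # pid -> 7 time-related columns
    automode_counts: dict[str, dict[str, int]]  # pid -> date -> count
    kinematic_features: list[str]
    schema: FeatureSchema
    exclusion_report: ingest.ExclusionReport
    removal_log: list[dict] = field(default_factory=list)
    target: int = TARGET_LENGTH_DEFAULT

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])


def prepare_cohort(
    rounds: pd.DataFrame,
    patients: pd.DataFrame,
    n_games: int = 7,
    target: int = TARGET_LENGTH_DEFAULT,
    min_attendances: int = ingest.MIN_ATTENDANCES_DEFAULT,
    mutuality_threshold: float = ingest.MUTUALITY_THRESHOLD_DEFAULT,
    game_feature_masks: dict[int, tuple[str, ...]] | None = None,
    tie_break: str = "small_gap_first",
) -> PreparedCohort:
    """Run every ingest/harmonization stage on raw per-round logs."""
    active, auto_counts_df = ingest.exclude_automode_rounds(rounds)
    sessions = ingest.average_rounds_to_sessions(active)
    retained_features = ingest.filter_features_by_mutuality(
        sessions, game_feature_masks, n_games=n_games, threshold=mutuality_threshold
    )
    sessions = ingest.fill_missing_values(sessions, retained_features)
    retained_patients, sessions, report = ingest.apply_patient_exclusions(
        patients, sessions, min_attendances=min_attendances
    )
    logger.info(
        "exclusions: %d in, %d no post-assessment, %d too few attendances, %d retained",
        report.n_input_patients, report.n_excluded_no_post_assessment,
        report.n_excluded_too_few_attendances, report.n_retained,
    )
    auto_counts: dict[str, dict[str, int]] = {}
    for _, row in auto_counts_df.iterrows():
        auto_counts.setdefault(row["patient_id"], {})[row["date"]] = int(
            row["automode_count"]
        )

    schema = FeatureSchema(kinematic=tuple(retained_features), n_games=n_games)
    series: dict[str, pd.DataFrame] = {}
    time_feats: dict[str, pd.DataFrame] = {}
    removal_log: list[dict] = []
    for pid, grp in sessions.groupby("patient_id", sort=False):
        hs = harmonize.harmonize_series(
            grp.reset_index(drop=True), target=target, tie_break=tie_break
        )
        removal_log.extend(harmonize.removals_to_records(pid, hs))
        kept = hs.sessions
        series[pid] = kept
        # Time features reflect the final grid (computed post-shrinking).
        time_feats[pid] = features.compute_time_related_features(
            kept, auto_counts.get(pid, {})
        )
    return PreparedCohort(
        patients=retained_patients,
        series=series,
        time_features=time_feats,
        automode_counts=auto_counts,
        kinematic_features=retained_features,
        schema=schema,
        exclusion_report=report,
        removal_log=removal_log,
        target=target,
    )


def fit_fold_normalizer(
    prep: PreparedCohort, train_ids: list[str]
) -> normalize.NormalizationState:
    """Fit cohort-level maxima on the training patients of one fold."""
    train_sessions = pd.concat([prep.series[pid] for pid in train_ids])
    train_patients = prep.patients[prep.patients["patient_id"].isin(train_ids)]
    return normalize.fit_normalizer(
        train_sessions,
        train_patients,
        prep.kinematic_features,
        {pid: prep.time_features[pid] for pid in train_ids},
    )


def build_cohort_tensor(
    prep: PreparedCohort,
    patient_ids: list[str],
    state: normalize.NormalizationState,
) -> CohortTensor:
    """Normalize and stack the given patients into one cohort tensor."""
    patient_rows = prep.patients.set_index("patient_id")
    out = []
    for pid in patient_ids:
        record = patient_rows.loc[pid]
        demo = normalize.normalize_demographics(record, state)
        sess = prep.series[pid]
        tf_norm = normalize.normalize_time_features(
            prep.time_features[pid], pid, state
        ).to_numpy()
        m = len(sess)
        steps = np.zeros((m, prep.schema.width))
        classes = np.zeros((m, len(ROBOT_PARAMETERS)), dtype=int)
        kin_cols = sess[prep.kinematic_features].to_numpy()
        for i in range(m):
            row = sess.iloc[i]
            levels = {p: row[p] for p in ROBOT_PARAMETERS}
            steps[i] = tensors.build_feature_vector(
                demographics=demo,
                kinematics=normalize.normalize_kinematics(
                    kin_cols[i], int(row["game_id"]), prep.kinematic_features, state
                ),
                robot_params=normalize.normalize_robot_params(levels),
                game_onehot=features.encode_game_choice(
                    int(row["game_id"]), prep.schema.n_games
                ),
                time_features=tf_norm[i],
                schema=prep.schema,
            )
            classes[i] = [
                level_to_index(p, levels[p]) for p in ROBOT_PARAMETERS
            ]
        label = normalize.normalize_clinical_scores(
            {s: record[f"{s}_t1"] for s in CLINICAL_SCALES}, state
        )
        out.append((pid, steps, label, classes))
    return tensors.assemble_cohort_tensor(out, prep.schema, target=prep.target)


# ---------------------------------------------------------------------------
# Reference predictors (sanity baselines for the recovery checks)


def cohort_mean_predictions(
    train: CohortTensor, test: CohortTensor
) -> np.ndarray:
    """Constant predictor: the training cohort's mean discharge triple at
    every step."""
    mean = train.labels.mean(axis=0)
    P, T, _ = test.values.shape
    return np.broadcast_to(mean, (P, T, 3)).copy()


def majority_class(labels: np.ndarray) -> int:
    values, counts = np.unique(labels, return_counts=True)
    return int(values[np.argmax(counts)])


# ---------------------------------------------------------------------------
# Permutation-importance wiring


def outcome_importance(
    model: models.OutcomeModel,
    test: CohortTensor,
    n_repeats: int = 10,
    seed: int = 0,
    mode: str = "trajectory",
) -> np.ndarray:
    """Normalized importances for the outcome model (RMSE degradation on a
    test tensor, whole-trajectory shuffling across patients)."""
    mask = test.mask
    labels = test.labels

    def metric(values: np.ndarray) -> float:
        pred = np.clip(model.net.forward(values, training=False), 0.0, 1.0)
        errs = []
        for si in range(len(CLINICAL_SCALES)):
            y = np.repeat(labels[:, si][:, None], values.shape[1], axis=1)[mask]
            errs.append(evaluation.rmse(y, pred[:, :, si][mask]))
        return float(np.mean(errs))

    return evaluation.permutation_importance(
        metric, test.values, test.values.shape[2],
        n_repeats=n_repeats, seed=seed, mode=mode,
    )


def difficulty_importance(
    model: models.DifficultyModel,
    dataset: LookbackDataset,
    n_repeats: int = 10,
    seed: int = 0,
    mode: str = "trajectory",
) -> np.ndarray:
    """Normalized importances for one difficulty model (accuracy drop on a
    test window set)."""
    y = dataset.label_for(model.config.parameter)

    def metric(windows: np.ndarray) -> float:
        pred = np.argmax(
            nn_softmax(model.net.forward(windows, training=False)), axis=1
        )
        return 1.0 - evaluation.multiclass_accuracy(y, pred)

    return evaluation.permutation_importance(
        metric, dataset.windows, dataset.windows.shape[2],
        n_repeats=n_repeats, seed=seed, mode=mode,
    )


def nn_softmax(logits: np.ndarray) -> np.ndarray:
    from . import nn

    return nn.softmax(logits)


# ---------------------------------------------------------------------------
# Cross-validated evaluation


def run_cross_validation(
    prep: PreparedCohort,
    k: int = 5,
    seed: int = 42,
    outcome_config: models.OutcomeModelConfig | None = None,
    difficulty_configs: dict[str, models.DifficultyModelConfig] | None = None,
    rf_config: models.RFConfig | None = None,
    with_rf: bool = True,
    with_importance: bool = False,
    importance_repeats: int = 5,
) -> evaluation.EvalReport:
    """Train and evaluate every model on shared patient-level folds.

    The normalizer is fitted per fold on training patients only. Returns an
    EvalReport with per-fold pooled RMSE/MAE (normalized units) per clinical
    scale, OA / weighted F1 per robot parameter, MCID groups, paired
    Wilcoxon comparisons against the random-forest baselines and, when
    requested, last-fold permutation importances.
    """
    outcome_config = outcome_config or models.OutcomeModelConfig(seed=seed)
    difficulty_configs = difficulty_configs or models.DIFFICULTY_PRESETS
    rf_config = rf_config or models.RFConfig(seed=seed)
    plan = models.make_cv_folds(prep.patient_ids, k, seed)
    report = evaluation.EvalReport()

    for fold in range(plan.k):
        train_ids, test_ids = plan.split(fold)
        state = fit_fold_normalizer(prep, train_ids)
        train = build_cohort_tensor(prep, train_ids, state)
        test = build_cohort_tensor(prep, test_ids, state)

        # --- outcome task -------------------------------------------------
        om = models.OutcomeModel(
            models.OutcomeModelConfig(
                **{**outcome_config.__dict__, "seed": outcome_config.seed + fold}
            ),
            input_dim=prep.schema.width,
        ).fit(train)
        pred = om.predict_normalized(test)
        report.add_outcome_fold(
            "lstm",
            evaluation.aggregate_session_errors(
                pred, test.labels, test.mask, test.patient_ids, fold=fold
            ),
        )
        if with_rf:
            rf = models.RFOutcomeBaseline(rf_config).fit(train)
            report.add_outcome_fold(
                "random_forest",
                evaluation.aggregate_session_errors(
                    rf.predict_normalized(test), test.labels, test.mask,
                    test.patient_ids, fold=fold,
                ),
            )

        # --- recommendation task -----------------------------------------
        dst_models: dict[str, models.DifficultyModel] = {}
        test_windows: dict[str, LookbackDataset] = {}
        train_windows: dict[str, LookbackDataset] = {}
        for param in ROBOT_PARAMETERS:
            cfg = difficulty_configs[param]
            cfg = models.DifficultyModelConfig(
                **{**cfg.__dict__, "seed": cfg.seed + fold}
            )
            tr_ds = tensors.build_lookback_windows(train, cfg.lookback)
            te_ds = tensors.build_lookback_windows(test, cfg.lookback)
            train_windows[param], test_windows[param] = tr_ds, te_ds
            dm = models.DifficultyModel(cfg, input_dim=prep.schema.width)
            dm.fit(tr_ds.windows, tr_ds.label_for(param))
            dst_models[param] = dm
            y_true = te_ds.label_for(param)
            y_pred = dm.predict_classes(te_ds.windows)
            report.add_recommendation_fold(
                "lstm", param, fold,
                evaluation.multiclass_accuracy(y_true, y_pred),
                evaluation.multiclass_f1(y_true, y_pred),
            )
        if with_rf:
            for param in ROBOT_PARAMETERS:
                clf = models.RFDifficultyBaseline(param, rf_config)
                tr_ds = train_windows[param]
                clf.fit(tr_ds.windows, tr_ds.label_for(param))
                te_ds = test_windows[param]
                y_true = te_ds.label_for(param)
                y_pred = clf.predict_classes(te_ds.windows)
                report.add_recommendation_fold(
                    "random_forest", param, fold,
                    evaluation.multiclass_accuracy(y_true, y_pred),
                    evaluation.multiclass_f1(y_true, y_pred),
                )

        if with_importance and fold == plan.k - 1:
            names = list(prep.schema.columns)
            imp = outcome_importance(om, test, n_repeats=importance_repeats, seed=seed)
            report.importance["outcome"] = dict(zip(names, imp.tolist()))
            for param, dm in dst_models.items():
                imp = difficulty_importance(
                    dm, test_windows[param], n_repeats=importance_repeats, seed=seed
                )
                report.importance[param] = dict(zip(names, imp.tolist()))

    if with_rf:
        for scale in CLINICAL_SCALES:
            a = [f.rmse[scale] for f in report.outcome["lstm"]]
            b = [f.rmse[scale] for f in report.outcome["random_forest"]]
            if len(a) >= 5:
                report.comparisons[f"rmse_{scale}_lstm_vs_rf"] = evaluation.compare_models(a, b)
        for param in ROBOT_PARAMETERS:
            a = [r["oa"] for r in report.recommendation["lstm"][param]]
            b = [r["oa"] for r in report.recommendation["random_forest"][param]]
            if len(a) >= 5:
                report.comparisons[f"oa_{param}_lstm_vs_rf"] = evaluation.compare_models(a, b)
    return report
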