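"""Metrics, error stratification, permutation importance and report assembly.

Error metrics for the outcome task are RMSE and MAE computed at every valid
time-step against the discharge label, pooled over sessions and patients
within each test fold. The recommendation task reports overall accuracy
(correct / total) and the F1 score (harmonic mean of precision and recall;
multi-class values are averaged over classes, weighted by support by
default).

Per-patient prediction quality is stratified by the percentage difference

    PD = (y - mean(yhat)) / max_score,

positive when the model under-predicts, and grouped against the minimal
clinically important difference, operationalized as 10% of each scale:
within MCID when -0.10 <= PD <= 0.10, over-predicted when PD < -0.10,
under-predicted when PD > 0.10.

Permutation feature importance shuffles one feature's whole per-sample
trajectory across samples, measures the degradation of RMSE (outcome) or
accuracy (recommendation), clips negative degradations to zero and
normalizes the scores to sum to one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CLINICAL_SCALES, ROBOT_PARAMETERS, SCALE_MAXIMA

MCID_FRACTION = 0.10


# ---------------------------------------------------------------------------
# Elementary metrics


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("true and predicted vectors differ in length")
    if y.size == 0:
        raise ValueError("empty prediction pair")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root of the mean squared difference."""
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute difference."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def overall_accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    return (counts.tp + counts.tn) / counts.total


def f1(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 (with a warning) when both
    degenerate."""
    p, r = counts.precision, counts.recall
    if p + r == 0.0:
        warnings.warn("precision + recall is zero; defining F1 as 0")
        return 0.0
    return 2.0 * p * r / (p + r)


def multiclass_accuracy(y_true, y_pred) -> float:
    """Correctly classified cases over all cases."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(y_true == y_pred))


def multiclass_f1(y_true, y_pred, average: str = "weighted") -> float:
    """Per-class one-vs-rest F1, averaged over classes (weighted by class
    support by default; ``average="macro"`` for the unweighted mean)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    scores, supports = [], []
    for c in classes:
        counts = confusion_counts(y_true, y_pred, c)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores.append(f1(counts))
        supports.append(int(np.sum(y_true == c)))
    if average == "macro":
        return float(np.mean(scores))
    if average == "weighted":
        total = sum(supports)
        if total == 0:
            raise ValueError("no true labels")
        return float(sum(s * w for s, w in zip(scores, supports)) / total)
    raise ValueError(f"unknown average {average!r}")


# ---------------------------------------------------------------------------
# Percentage difference and MCID stratification


@dataclass(frozen=True)
class PDResult:
    y: float
    yhat_mean: float
    max_score: float
    pd: float


def percentage_difference(y: float, yhat_mean: float, max_score: float) -> PDResult:
    """(true discharge score - mean prediction) / scale max; positive means
    the model under-predicted."""
    if max_score <= 0:
        raise ValueError("max_score must be positive")
    return PDResult(
        y=float(y), yhat_mean=float(yhat_mean), max_score=float(max_score),
        pd=(float(y) - float(yhat_mean)) / float(max_score),
    )


def assign_mcid_group(pd_value: float) -> str:
    """within | over_predicted | under_predicted, with inclusive +-10%
    boundaries for the within group."""
    if not np.isfinite(pd_value):
        raise ValueError("PD must be finite")
    if pd_value < -MCID_FRACTION:
        return "over_predicted"
    if pd_value > MCID_FRACTION:
        return "under_predicted"
    return "within"


# ---------------------------------------------------------------------------
# Fold-level aggregation


@dataclass
class FoldOutcomeMetrics:
    """Pooled per-step errors of one model on one test fold, per scale
    (normalized 0-1 units)."""

    fold: int
    rmse: dict[str, float]
    mae: dict[str, float]
    patient_pd: dict[str, dict[str, float]]  # scale -> pid -> PD
    patient_mcid: dict[str, dict[str, str]]  # scale -> pid -> group


def aggregate_session_errors(
    predictions: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    patient_ids: list[str],
    fold: int = 0,
) -> FoldOutcomeMetrics:
    """Pool per-step errors over all sessions and patients of a test fold.

    ``predictions`` (P, T, 3) normalized per-step outputs; ``labels`` (P, 3)
    normalized discharge scores; ``mask`` (P, T). Also stores each
    patient's mean prediction for the PD / MCID stratification.
    """
    if mask.sum() == 0:
        raise ValueError("empty fold: no valid steps to evaluate")
    rmse_d, mae_d, pd_d, grp_d = {}, {}, {}, {}
    for si, scale in enumerate(CLINICAL_SCALES):
        ytrue, yhat = [], []
        pd_d[scale], grp_d[scale] = {}, {}
        for p, pid in enumerate(patient_ids):
            m = mask[p].astype(bool)
            if not m.any():
                continue
            step_preds = predictions[p, m, si]
            ytrue.append(np.full(step_preds.shape, labels[p, si]))
            yhat.append(step_preds)
            res = percentage_difference(
                y=labels[p, si] * SCALE_MAXIMA[scale],
                yhat_mean=float(step_preds.mean()) * SCALE_MAXIMA[scale],
                max_score=SCALE_MAXIMA[scale],
            )
            pd_d[scale][pid] = res.pd
            grp_d[scale][pid] = assign_mcid_group(res.pd)
        ytrue = np.concatenate(ytrue)
        yhat = np.concatenate(yhat)
        rmse_d[scale] = rmse(ytrue, yhat)
        mae_d[scale] = mae(ytrue, yhat)
    return FoldOutcomeMetrics(
        fold=fold, rmse=rmse_d, mae=mae_d, patient_pd=pd_d, patient_mcid=grp_d
    )


def summarize_folds(values: list[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "std": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


@dataclass
class EvalReport:
    """Per-fold metrics for every model plus their Mean+-Std / Min / Max
    aggregates, the MCID stratification and importance scores."""

    outcome: dict[str, list[FoldOutcomeMetrics]] = field(default_factory=dict)
    recommendation: dict[str, dict[str, list[dict]]] = field(default_factory=dict)
    importance: dict[str, dict[str, float]] = field(default_factory=dict)
    comparisons: dict[str, float] = field(default_factory=dict)

    def add_outcome_fold(self, model: str, metrics: FoldOutcomeMetrics) -> None:
        self.outcome.setdefault(model, []).append(metrics)

    def add_recommendation_fold(
        self, model: str, parameter: str, fold: int, oa: float, f1_score: float
    ) -> None:
        self.recommendation.setdefault(model, {}).setdefault(parameter, []).append(
            {"fold": fold, "oa": oa, "f1": f1_score}
        )

    def outcome_summary(self, model: str) -> dict:
        folds = self.outcome[model]
        out = {}
        for scale in CLINICAL_SCALES:
            out[scale] = {
                "rmse": summarize_folds([f.rmse[scale] for f in folds]),
                "mae": summarize_folds([f.mae[scale] for f in folds]),
            }
        return out

    def recommendation_summary(self, model: str) -> dict:
        out = {}
        for param, rows in self.recommendation[model].items():
            out[param] = {
                "oa": summarize_folds([r["oa"] for r in rows]),
                "f1": summarize_folds([r["f1"] for r in rows]),
            }
        return out

    def mcid_table(self, model: str) -> dict[str, dict[str, str]]:
        """Patient -> MCID group per scale, pooled over test folds (each
        patient is in exactly one test fold)."""
        table: dict[str, dict[str, str]] = {s: {} for s in CLINICAL_SCALES}
        for fm in self.outcome.get(model, []):
            for scale in CLINICAL_SCALES:
                table[scale].update(fm.patient_mcid[scale])
        return table

    def to_dict(self) -> dict:
        return {
            "outcome": {
                m: {
                    "folds": [
                        {"fold": f.fold, "rmse": f.rmse, "mae": f.mae,
                         "patient_pd": f.patient_pd, "patient_mcid": f.patient_mcid}
                        for f in folds
                    ],
                    "summary": self.outcome_summary(m),
                }
                for m, folds in self.outcome.items()
            },
            "recommendation": {
                m: {"folds": params, "summary": self.recommendation_summary(m)}
                for m, params in self.recommendation.items()
            },
            "importance": self.importance,
            "comparisons": self.comparisons,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary_table(self) -> pd.DataFrame:
        """Long-format table of Mean/Std/Min/Max per model, task and metric."""
        rows = []
        for model in self.outcome:
            for scale, mets in self.outcome_summary(model).items():
                for metric, agg in mets.items():
                    rows.append({"model": model, "target": scale, "metric": metric, **agg})
        for model in self.recommendation:
            for param, mets in self.recommendation_summary(model).items():
                for metric, agg in mets.items():
                    rows.append({"model": model, "target": param, "metric": metric, **agg})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Permutation importance


def permutation_importance(
    predict_metric,
    X: np.ndarray,
    n_features: int,
    n_repeats: int = 10,
    seed: int = 0,
    mode: str = "trajectory",
) -> np.ndarray:
    """Normalized permutation importance over the feature axis of ``X``.

    ``predict_metric(X) -> float`` must return the model's error-like score
    on ``X`` (higher = worse, e.g. RMSE or 1 - accuracy). For each feature
    the values are shuffled across samples — by default as whole per-sample
    trajectories, preserving within-series temporal coherence
    (``mode="per_step"`` shuffles each time-step independently) — and the
    mean degradation over ``n_repeats`` is recorded. Negative degradations
    are clipped to zero before normalizing the scores to sum to one.
    """
    if mode not in ("trajectory", "per_step"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    baseline = predict_metric(X)
    raw = np.zeros(n_features)
    N = X.shape[0]
    for j in range(n_features):
        deg = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            if mode == "trajectory":
                Xp[..., j] = Xp[rng.permutation(N), ..., j]
            else:
                for t in range(X.shape[1]):
                    Xp[:, t, j] = Xp[rng.permutation(N), t, j]
            deg += predict_metric(Xp) - baseline
        raw[j] = deg / n_repeats
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total == 0.0:
        return clipped  # model ignores every feature
    return clipped / total


def top_features(
    importances: np.ndarray, feature_names: list[str], k: int = 10
) -> list[tuple[str, float]]:
    order = np.argsort(importances)[::-1][:k]
    return [(feature_names[i], float(importances[i])) for i in order]


# ---------------------------------------------------------------------------
# Model comparison


def compare_models(metric_a: list[float], metric_b: list[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value over fold-level metric
    pairs (the choice of test is a package decision; the comparison context
    only reports descriptive deltas alongside it)."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need >= 5 paired fold values")
    if np.allclose(a, b):
        warnings.warn("all fold pairs tied; reporting p = 1")
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
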