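"""Invertible 0-1 normalization of all feature groups.

Four schemes, each with its fitted state recorded so transforms are exactly
reproducible and invertible:

* demographics — age divided by the cohort maximum; gender already 0/1;
  latency log-transformed (log1p, natural base) then divided by the cohort
  maximum of the transformed values;
* kinematic features — divided by the per-(game, feature) maximum of the
  training cohort, so the best-performing patients define the reference
  scale of each game; out-of-range test values are clipped to 1;
* robot parameters — ordinal levels mapped Low/Mid/High -> 1/2/3 (viscosity
  Low/High -> 1/2) and divided by the top level;
* time-related features — divided by each patient's own per-feature maximum,
  so the unit is the patient's personal schedule rather than the cohort's.

Clinical scores are divided by their scale maxima (ARAT 57, FMA 66, MI 100)
with an exact inverse.

Maxima are fitted on training folds only; per-patient time-feature maxima
involve no cross-patient information and are computed for whichever patient
is being transformed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .schema import (
    CLINICAL_SCALES,
    PARAMETER_LEVELS,
    ROBOT_PARAMETERS,
    SCALE_MAXIMA,
    TIME_FEATURES,
)

ROBOT_LEVEL_VALUE = {
    p: {lvl: i + 1 for i, lvl in enumerate(levels)}
    for p, levels in PARAMETER_LEVELS.items()
}
ROBOT_LEVEL_DIVISOR = {p: len(levels) for p, levels in PARAMETER_LEVELS.items()}


def _safe_max(values: np.ndarray, what: str) -> float:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    m = float(values.max()) if values.size else 0.0
    if m <= 0.0:
        logger.warning("all-zero %s; recording unit scale (no-op normalization)", what)
        return 1.0
    return m


@dataclass
class NormalizationState:
    """All fitted maxima needed to transform and exactly invert."""

    age_max: float = 1.0
    latency_log_max: float = 1.0
    kinematic_max: dict[tuple[int, str], float] = field(default_factory=dict)
    time_max: dict[str, dict[str, float]] = field(default_factory=dict)  # pid -> feat -> max
    scale_max: dict[str, float] = field(default_factory=lambda: dict(SCALE_MAXIMA))

    def to_json(self, path) -> None:
        payload = {
            "age_max": self.age_max,
            "latency_log_max": self.latency_log_max,
            "kinematic_max": [
                {"game": g, "feature": f, "max": m}
                for (g, f), m in sorted(self.kinematic_max.items())
            ],
            "time_max": self.time_max,
            "scale_max": self.scale_max,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "NormalizationState":
        d = json.loads(Path(path).read_text())
        return cls(
            age_max=d["age_max"],
            latency_log_max=d["latency_log_max"],
            kinematic_max={
                (e["game"], e["feature"]): e["max"] for e in d["kinematic_max"]
            },
            time_max={p: dict(v) for p, v in d["time_max"].items()},
            scale_max=dict(d["scale_max"]),
        )


def fit_normalizer(
    train_sessions: pd.DataFrame,
    train_patients: pd.DataFrame,
    kinematic_features: list[str],
    time_features_by_patient: dict[str, pd.DataFrame] | None = None,
) -> NormalizationState:
    """Fit all maxima on a training cohort.

    ``time_features_by_patient`` may pre-register per-patient time-feature
    maxima; otherwise they are registered lazily at transform time.
    """
    if len(train_patients) == 0:
        raise ValueError("training cohort is empty")
    state = NormalizationState()
    state.age_max = _safe_max(train_patients["age"].to_numpy(), "age")
    state.latency_log_max = _safe_max(
        np.log1p(train_patients["latency_days"].to_numpy()), "log-latency"
    )
    for game, grp in train_sessions.groupby("game_id"):
        for feat in kinematic_features:
            state.kinematic_max[(int(game), feat)] = _safe_max(
                grp[feat].to_numpy(), f"kinematic {feat} (game {game})"
            )
    if time_features_by_patient:
        for pid, tf in time_features_by_patient.items():
            register_patient_time_max(state, pid, tf)
    return state


def register_patient_time_max(
    state: NormalizationState, patient_id: str, time_features: pd.DataFrame
) -> None:
    state.time_max[patient_id] = {
        feat: _safe_max(time_features[feat].to_numpy(), f"time feature {feat}")
        for feat in TIME_FEATURES
    }


def normalize_demographics(record, state: NormalizationState) -> np.ndarray:
    """(age, gender, latency) -> three values in [0, 1]."""
    age = np.clip(float(record["age"]) / state.age_max, 0.0, 1.0)
    gender = float(record["gender"])
    latency = np.clip(
        np.log1p(float(record["latency_days"])) / state.latency_log_max, 0.0, 1.0
    )
    return np.array([age, gender, latency])


def normalize_kinematics(
    values: np.ndarray, game_id: int, features: list[str], state: NormalizationState
) -> np.ndarray:
    """Divide by the per-(game, feature) training maxima; clip to [0, 1]."""
    maxima = np.array(
        [state.kinematic_max.get((int(game_id), f), 1.0) for f in features]
    )
    return np.clip(np.asarray(values, dtype=float) / maxima, 0.0, 1.0)


def normalize_robot_params(levels: dict[str, str]) -> np.ndarray:
    """Ordinal level -> value/top: stiffness & weight in {1/3, 2/3, 1},
    viscosity in {1/2, 1}."""
    out = []
    for p in ROBOT_PARAMETERS:
        lvl = levels[p]
        if lvl not in ROBOT_LEVEL_VALUE[p]:
            raise ValueError(f"unknown {p} level {lvl!r}")
        out.append(ROBOT_LEVEL_VALUE[p][lvl] / ROBOT_LEVEL_DIVISOR[p])
    return np.array(out)


def normalize_time_features(
    time_features: pd.DataFrame, patient_id: str, state: NormalizationState
) -> pd.DataFrame:
    """Divide each time feature by the patient's own maximum of it."""
    if patient_id not in state.time_max:
        register_patient_time_max(state, patient_id, time_features)
    maxima = state.time_max[patient_id]
    out = time_features.copy()
    for feat in TIME_FEATURES:
        out[feat] = time_features[feat] / maxima[feat]
    return out


def normalize_clinical_scores(scores, state: NormalizationState | None = None) -> np.ndarray:
    """(ARAT, FMA, MI) -> fractions of the scale maxima."""
    scale_max = state.scale_max if state is not None else SCALE_MAXIMA
    out = []
    for scale in CLINICAL_SCALES:
        v = float(scores[scale])
        mx = scale_max[scale]
        if not 0.0 <= v <= mx:
            raise ValueError(f"{scale} score {v} outside [0, {mx}]")
        out.append(v / mx)
    return np.array(out)


def denormalize_clinical_scores(
    values: np.ndarray, state: NormalizationState | None = None
) -> np.ndarray:
    """Exact inverse of :func:`normalize_clinical_scores` (last axis =
    (ARAT, FMA, MI))."""
    scale_max = state.scale_max if state is not None else SCALE_MAXIMA
    maxima = np.array([scale_max[s] for s in CLINICAL_SCALES])
    return np.asarray(values, dtype=float) * maxima
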