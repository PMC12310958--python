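"""From per-round robot logs to clean per-patient session series.

The raw grain is one played game round. Processing steps, in order:

1. drop automode (passive) rounds, keeping their per-(patient, date) counts;
2. average same-(patient, date, game) rounds into one "session" — the
   time-step of a patient's series — and order sessions chronologically;
3. keep only kinematic features shared by more than 70% of the games
   ("mutuality" filter);
4. fill remaining missing values from the same patient's same-date sessions,
   falling back to front-fill (then back-fill, then zero);
5. exclude patients with fewer than 10 distinct attendance dates or without
   discharge (T1) clinical scores.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as _features
from .schema import CLINICAL_SCALES, KINEMATIC_FEATURES, ROBOT_PARAMETERS

logger = logging.getLogger(__name__)

#: Columns of the rounds table that are not kinematic features.
ROUND_META_COLUMNS = (
    "patient_id",
    "date",
    "game_id",
    "automode",
    "stiffness",
    "weight",
    "viscosity",
)

MIN_ATTENDANCES_DEFAULT = 10
MUTUALITY_THRESHOLD_DEFAULT = 0.70


def kinematic_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in ROUND_META_COLUMNS and c not in ("day", "n_rounds")]


def read_rounds_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ROUND_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rounds table missing columns: {missing}")
    return df


def read_patients_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for scale in CLINICAL_SCALES:
        for col in (f"{scale}_t0", f"{scale}_t1"):
            if col not in df.columns:
                raise ValueError(f"patients table missing column {col}")
    return df


def exclude_automode_rounds(
    rounds: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split off automode rounds; return (active rounds, per-(patient, date) counts).

    Every removed round is accounted for in the counts, so rounds are
    conserved: actives + counted automodes == input.
    """
    auto = rounds["automode"].astype(bool)
    active = rounds.loc[~auto].reset_index(drop=True)
    counts = (
        rounds.loc[auto]
        .groupby(["patient_id", "date"], as_index=False)
        .size()
        .rename(columns={"size": "automode_count"})
    )
    return active, counts


def average_rounds_to_sessions(rounds: pd.DataFrame) -> pd.DataFrame:
    """Average same-(patient, date, game) rounds into one session record.

    Kinematic values are arithmetic means over the rounds where the feature
    is present; robot parameter levels follow the nearest-value rule (see
    :func:`rehabdst.features.attach_robot_parameters`). The result is sorted
    chronologically per patient, with same-date sessions kept in stable
    input order, and carries an integer ``day`` offset from the patient's
    first session plus the ``n_rounds`` averaged.
    """
    if rounds.empty:
        return pd.DataFrame(
            columns=["patient_id", "date", "day", "game_id", "n_rounds", *ROBOT_PARAMETERS]
        )
    feats = kinematic_columns(rounds)
    df = rounds.reset_index(drop=True)
    df["_order"] = np.arange(len(df))
    out_rows = []
    grouped = df.groupby(["patient_id", "date", "game_id"], sort=False)
    for (pid, date, game), grp in grouped:
        grp = grp.sort_values("_order")
        row = {
            "patient_id": pid,
            "date": date,
            "game_id": game,
            "n_rounds": len(grp),
            "_order": int(grp["_order"].iloc[0]),
        }
        row.update(_features.attach_robot_parameters(grp))
        means = grp[feats].mean(axis=0, skipna=True)
        row.update(means.to_dict())
        out_rows.append(row)
    sessions = pd.DataFrame(out_rows)
    days = pd.to_datetime(sessions["date"]).map(pd.Timestamp.toordinal)
    sessions["day"] = days - days.groupby(sessions["patient_id"]).transform("min")
    sessions = (
        sessions.sort_values(["patient_id", "day", "_order"], kind="stable")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    cols = ["patient_id", "date", "day", "game_id", "n_rounds", *ROBOT_PARAMETERS, *feats]
    return sessions[cols]


def filter_features_by_mutuality(
    sessions: pd.DataFrame,
    game_feature_masks: dict[int, tuple[str, ...]] | None = None,
    n_games: int = 7,
    threshold: float = MUTUALITY_THRESHOLD_DEFAULT,
) -> list[str]:
    """Kinematic features shared by strictly more than ``threshold`` of games.

    A feature belongs to a game's feature set if the game's mask lists it
    (when masks are given) or if any session of that game reports it
    (observational estimate). The denominator is the configured number of
    games — the filter is a dataset-level schema decision, not a per-patient
    one. The returned order follows the canonical schema order, with any
    non-canonical survivors appended alphabetically.
    """
    if sessions.empty:
        raise ValueError("cannot estimate mutuality from an empty session set")
    feats = kinematic_columns(sessions)
    if game_feature_masks is not None:
        support = {
            f: sum(1 for g in range(1, n_games + 1) if f in game_feature_masks.get(g, ()))
            for f in feats
        }
    else:
        support = {
            f: int(sessions.loc[sessions[f].notna(), "game_id"].nunique()) for f in feats
        }
    retained = [f for f in feats if support[f] / n_games > threshold]
    canonical = [f for f in KINEMATIC_FEATURES if f in retained]
    extra = sorted(f for f in retained if f not in KINEMATIC_FEATURES)
    return canonical + extra


def fill_missing_values(
    sessions: pd.DataFrame, retained_features: list[str]
) -> pd.DataFrame:
    """Complete every retained feature for every session.

    Fill order per missing (patient, date, game, feature): the mean of the
    patient's other same-date sessions (any game); else the most recent
    prior value (front-fill); else the next available value (back-fill);
    else 0 with a warning.
    """
    df = sessions.copy()
    filled = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.copy()
        for feat in retained_features:
            col = grp[feat]
            if col.notna().all():
                continue
            date_mean = col.groupby(grp["day"]).transform("mean")
            col = col.fillna(date_mean)
            col = col.ffill().bfill()
            if col.isna().any():
                logger.warning(
                    "feature %s never observed for patient %s; filled with 0", feat, pid
                )
                col = col.fillna(0.0)
            grp[feat] = col
        filled.append(grp)
    return pd.concat(filled).loc[df.index] if filled else df


@dataclass
class ExclusionReport:
    """Bookkeeping of the two patient exclusion criteria."""

    n_input_patients: int
    n_excluded_no_post_assessment: int
    n_excluded_too_few_attendances: int
    n_retained: int
    reasons: dict[str, str] = field(default_factory=dict)  # pid -> reason code

    def __post_init__(self):
        total = (
            self.n_retained
            + self.n_excluded_no_post_assessment
            + self.n_excluded_too_few_attendances
        )
        if total != self.n_input_patients:
            raise ValueError("exclusion counts do not reconcile with input size")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_input_patients": self.n_input_patients,
                    "n_excluded_no_post_assessment": self.n_excluded_no_post_assessment,
                    "n_excluded_too_few_attendances": self.n_excluded_too_few_attendances,
                    "n_retained": self.n_retained,
                    "reasons": self.reasons,
                },
                indent=2,
            )
        )


def apply_patient_exclusions(
    patients: pd.DataFrame,
    sessions: pd.DataFrame,
    min_attendances: int = MIN_ATTENDANCES_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionReport]:
    """Retain patients with >= ``min_attendances`` distinct active dates and
    complete discharge scores.

    A patient failing both criteria is counted once under the missing
    post-assessment reason (that criterion takes precedence).
    """
    t1_cols = [f"{s}_t1" for s in CLINICAL_SCALES]
    attendance = sessions.groupby("patient_id")["date"].nunique()
    reasons: dict[str, str] = {}
    keep: list[bool] = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        has_post = bool(pd.notna(row[t1_cols]).all())
        n_dates = int(attendance.get(pid, 0))
        if not has_post:
            reasons[pid] = "no_post_assessment"
            keep.append(False)
        elif n_dates < min_attendances:
            reasons[pid] = "too_few_attendances"
            keep.append(False)
        else:
            keep.append(True)
    retained = patients.loc[keep].reset_index(drop=True)
    retained_ids = set(retained["patient_id"])
    report = ExclusionReport(
        n_input_patients=len(patients),
        n_excluded_no_post_assessment=sum(
            1 for r in reasons.values() if r == "no_post_assessment"
        ),
        n_excluded_too_few_attendances=sum(
            1 for r in reasons.values() if r == "too_few_attendances"
        ),
        n_retained=len(retained),
        reasons=reasons,
    )
    kept_sessions = sessions[sessions["patient_id"].isin(retained_ids)].reset_index(
        drop=True
    )
    return retained, kept_sessions, report
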