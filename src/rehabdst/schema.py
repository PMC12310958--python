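"""Canonical feature schema for the per-time-step model input.

Every time-step (one per-day, per-game "session") is represented by a fixed
36-column vector split into five groups:

* demographics (3): age, gender, latency — constant over a patient's series;
* kinematic features (16): scalar summaries the robot extracts per game round
  (speeds, work terms, smoothness, durations, ...);
* robot parameters (3): stiffness / weight / viscosity difficulty levels;
* game choice (7): one-hot indicator of which serious game was played;
* time-related features (7): calendar and counter features describing where
  the session sits inside the patient's therapy timeline.

The column order is fixed and serialized next to every tensor artifact so
downstream consumers (models, importance reports) can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

DEMOGRAPHIC_FEATURES: tuple[str, ...] = ("age", "gender", "latency")

#: The 16 kinematic scalars shared (mutuality > 70%) across the seven games.
KINEMATIC_FEATURES: tuple[str, ...] = (
    "userVelocityAvg",
    "workUserTotal",
    "workTanUserTotal",
    "precisionWork",
    "distanceTask",
    "autonomyDuration",
    "velocityNorm",
    "durationUser",
    "workTanRobot",
    "params",
    "workTanUserSelf",
    "overall",
    "calories",
    "timeUser",
    "smoothness_force",
    "smoothness_kin",
)

ROBOT_PARAMETERS: tuple[str, ...] = ("stiffness", "weight", "viscosity")

TIME_FEATURES: tuple[str, ...] = (
    "date_diff",
    "date_diff_session",
    "remaining_day_of_therapy",
    "number_of_sessions",
    "total_sessions_day",
    "total_sessions_incr",
    "automode_sessions",
)

#: Ordinal level sets for the robot difficulty parameters.
STIFFNESS_LEVELS: tuple[str, ...] = ("Low", "Mid", "High")
WEIGHT_LEVELS: tuple[str, ...] = ("Low", "Mid", "High")
VISCOSITY_LEVELS: tuple[str, ...] = ("Low", "High")
PARAMETER_LEVELS: dict[str, tuple[str, ...]] = {
    "stiffness": STIFFNESS_LEVELS,
    "weight": WEIGHT_LEVELS,
    "viscosity": VISCOSITY_LEVELS,
}

#: Clinical scale maxima: ARAT in [0, 57], FMA in [0, 66], MI in [0, 100].
CLINICAL_SCALES: tuple[str, ...] = ("arat", "fma", "mi")
SCALE_MAXIMA: dict[str, float] = {"arat": 57.0, "fma": 66.0, "mi": 100.0}

DEFAULT_N_GAMES = 7
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered column layout of the per-time-step feature vector."""

    kinematic: tuple[str, ...] = KINEMATIC_FEATURES
    n_games: int = DEFAULT_N_GAMES
    version: int = SCHEMA_VERSION
    demographics: tuple[str, ...] = DEMOGRAPHIC_FEATURES
    robot_parameters: tuple[str, ...] = ROBOT_PARAMETERS
    time_related: tuple[str, ...] = TIME_FEATURES

    @property
    def game_columns(self) -> tuple[str, ...]:
        return tuple(f"game_{g}" for g in range(1, self.n_games + 1))

    @property
    def columns(self) -> tuple[str, ...]:
        return (
            self.demographics
            + self.kinematic
            + self.robot_parameters
            + self.game_columns
            + self.time_related
        )

    @property
    def width(self) -> int:
        return len(self.columns)

    # Group slices into the assembled vector, in schema order.
    @property
    def slices(self) -> dict[str, slice]:
        d = len(self.demographics)
        k = d + len(self.kinematic)
        r = k + len(self.robot_parameters)
        g = r + self.n_games
        t = g + len(self.time_related)
        return {
            "demographics": slice(0, d),
            "kinematic": slice(d, k),
            "robot_parameters": slice(k, r),
            "game_choice": slice(r, g),
            "time_related": slice(g, t),
        }

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "demographics": list(self.demographics),
            "kinematic": list(self.kinematic),
            "robot_parameters": list(self.robot_parameters),
            "game_columns": list(self.game_columns),
            "time_related": list(self.time_related),
            "width": self.width,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            kinematic=tuple(d["kinematic"]),
            n_games=len(d["game_columns"]),
            version=d.get("version", SCHEMA_VERSION),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FeatureSchema":
        return cls.from_dict(json.loads(Path(path).read_text()))


def level_to_index(parameter: str, level: str) -> int:
    """Map a difficulty level name to its 0-based ordinal class index."""
    levels = PARAMETER_LEVELS[parameter]
    try:
        return levels.index(level)
    except ValueError:
        raise ValueError(
            f"unknown {parameter} level {level!r}; expected one of {levels}"
        ) from None


def index_to_level(parameter: str, index: int) -> str:
    levels = PARAMETER_LEVELS[parameter]
    if not 0 <= index < len(levels):
        raise ValueError(f"{parameter} class index {index} out of range")
    return levels[index]
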