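"""Time-related features, game one-hot encoding, robot-parameter attachment.

Seven time-related features describe where a session sits inside the
patient's therapy timeline (all in days or counts, pre-normalization):

==========================  ====================================================
date_diff                   days between this session and the patient's first
date_diff_session           days between consecutive sessions (0 within a date)
remaining_day_of_therapy    declining time-step counter L..1 over the series
number_of_sessions          rounds of this game averaged into this session
total_sessions_day          sessions (any game) sharing this session's date
total_sessions_incr         running count of sessions up to and incl. this date
automode_sessions           automode rounds recorded on this session's date
==========================  ====================================================

``remaining_day_of_therapy`` counts down over time-steps, not calendar days,
and is computed on the final (post-harmonization) series so the counter
reflects the grid the models actually see.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import PARAMETER_LEVELS, ROBOT_PARAMETERS, TIME_FEATURES


def compute_time_related_features(
    patient_sessions: pd.DataFrame,
    automode_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """The 7 time-related features for one patient's chronological series.

    ``patient_sessions`` needs columns ``day`` (integer offset), ``date`` and
    ``n_rounds``; ``automode_counts`` maps date -> number of automode rounds
    recorded that date (missing dates count 0).
    """
    days = patient_sessions["day"].to_numpy()
    if np.any(np.diff(days) < 0):
        raise ValueError("patient sessions must be in chronological order")
    L = len(patient_sessions)
    automode_counts = automode_counts or {}
    date_diff = days - days[0] if L else days
    date_diff_session = np.concatenate([[0], np.diff(days)]) if L else days
    remaining = np.arange(L, 0, -1)
    day_counts = pd.Series(days).value_counts()
    total_sessions_day = np.array([day_counts[d] for d in days])
    total_sessions_incr = np.array(
        [int(np.sum(days <= d)) for d in days]
    )
    automode_sessions = np.array(
        [automode_counts.get(date, 0) for date in patient_sessions["date"]]
    )
    return pd.DataFrame(
        {
            "date_diff": date_diff,
            "date_diff_session": date_diff_session,
            "remaining_day_of_therapy": remaining,
            "number_of_sessions": patient_sessions["n_rounds"].to_numpy(),
            "total_sessions_day": total_sessions_day,
            "total_sessions_incr": total_sessions_incr,
            "automode_sessions": automode_sessions,
        },
        index=patient_sessions.index,
    )[list(TIME_FEATURES)]


def encode_game_choice(game_id: int, n_games: int = 7) -> np.ndarray:
    """One-hot indicator of the played serious game."""
    if not 1 <= game_id <= n_games:
        raise ValueError(f"game_id {game_id} out of range 1..{n_games}")
    v = np.zeros(n_games)
    v[game_id - 1] = 1.0
    return v


def attach_robot_parameters(rounds_of_session: pd.DataFrame) -> dict[str, str]:
    """Difficulty levels for a session averaged from several rounds.

    If all rounds agree the common level is used; on conflict the level of
    the chronologically last round wins (the therapist's most recent
    setting); a round lacking the parameter defers to the temporally nearest
    round carrying it. Raises if no round carries a parameter at all.
    """
    if len(rounds_of_session) == 0:
        raise ValueError("session must contain at least one round")
    out = {}
    for p in ROBOT_PARAMETERS:
        vals = rounds_of_session[p].dropna()
        if vals.empty:
            raise ValueError(f"no round of the session carries parameter {p!r}")
        level = str(vals.iloc[-1])
        if level not in PARAMETER_LEVELS[p]:
            raise ValueError(f"invalid {p} level {level!r}")
        out[p] = level
    return out
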