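"""Bring every patient series to a fixed number of time-points (default 64).

Short series are zero-padded at the end and the padding is masked out by the
models. Long series are shrunk by iteratively deleting single sessions so
that the temporal dimension stays balanced and game diversity is preserved:

1. partition the series into date groups (sessions sharing a calendar date);
2. rank groups by unique-game count, descending; break ties by the smaller
   day-gap to the temporally adjacent groups, then by earlier date;
3. count how often each game occurs over the *current* series (popularity);
4. from the top-ranked group remove the single session whose game is
   currently most popular (ties -> lowest game id);
5. recompute everything and repeat until the target length is reached.

Whether a tie between equally diverse date groups should favor the small or
the large adjacent gap is an open modelling choice; the default prunes the
denser region first (``tie_break="small_gap_first"``), with the opposite
order available behind the switch.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TARGET_LENGTH_DEFAULT = 64


@dataclass
class DateGroup:
    day: int
    positions: list[int]  # row positions into the current series
    games: list[int]
    min_adjacent_gap: float  # days to nearest neighboring group (inf if alone)

    @property
    def unique_games(self) -> int:
        return len(set(self.games))


@dataclass
class Removal:
    iteration: int
    day: int
    date: str
    game_id: int


@dataclass
class HarmonizedSeries:
    """A series on the fixed grid: kept sessions + suffix padding mask."""

    sessions: pd.DataFrame  # surviving sessions, chronological, len <= target
    target: int
    removals: list[Removal] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sessions)

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.target, dtype=bool)
        m[: self.length] = True
        return m


def build_date_groups(days: np.ndarray) -> list[DateGroup]:
    """Partition a chronological day vector into date groups with gap info."""
    unique_days = sorted(set(int(d) for d in days))
    groups = []
    for i, d in enumerate(unique_days):
        gaps = []
        if i > 0:
            gaps.append(d - unique_days[i - 1])
        if i < len(unique_days) - 1:
            gaps.append(unique_days[i + 1] - d)
        groups.append(
            DateGroup(
                day=d,
                positions=[int(p) for p in np.flatnonzero(days == d)],
                games=[],
                min_adjacent_gap=float(min(gaps)) if gaps else float("inf"),
            )
        )
    return groups


def pad_series(
    series: pd.DataFrame, target: int = TARGET_LENGTH_DEFAULT
) -> HarmonizedSeries:
    """Keep a short series as-is; padding slots are materialized later as
    all-zero feature rows flagged invalid by the mask."""
    if target <= 0:
        raise ValueError("target length must be positive")
    if len(series) > target:
        raise ValueError(
            f"series of length {len(series)} exceeds target {target}; use shrink_series"
        )
    if len(series) == 0:
        warnings.warn("padding an empty series; the patient should have been excluded")
    return HarmonizedSeries(sessions=series.reset_index(drop=True), target=target)


def shrink_series(
    series: pd.DataFrame,
    target: int = TARGET_LENGTH_DEFAULT,
    tie_break: str = "small_gap_first",
) -> HarmonizedSeries:
    """Iteratively delete sessions until the series has ``target`` rows.

    ``series`` must be one patient's chronological sessions with ``day``,
    ``date`` and ``game_id`` columns. Fully deterministic: group ties fall
    back to the earlier date and game-popularity ties to the lowest game id.
    """
    if target <= 0:
        raise ValueError("target length must be positive")
    if len(series) <= target:
        raise ValueError(
            f"series of length {len(series)} does not exceed target {target}; use pad_series"
        )
    if tie_break not in ("small_gap_first", "large_gap_first"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    gap_sign = 1.0 if tie_break == "small_gap_first" else -1.0

    current = series.reset_index(drop=True)
    removals: list[Removal] = []
    iteration = 0
    while len(current) > target:
        iteration += 1
        days = current["day"].to_numpy()
        games = current["game_id"].to_numpy()
        groups = build_date_groups(days)
        for g in groups:
            g.games = [int(games[p]) for p in g.positions]
        groups.sort(
            key=lambda g: (-g.unique_games, gap_sign * g.min_adjacent_gap, g.day)
        )
        top = groups[0]
        popularity = Counter(int(g) for g in games)
        victim_game = min(
            set(top.games), key=lambda g: (-popularity[g], g)
        )
        pos = next(p for p in top.positions if int(games[p]) == victim_game)
        removals.append(
            Removal(
                iteration=iteration,
                day=top.day,
                date=str(current["date"].iloc[pos]),
                game_id=victim_game,
            )
        )
        current = current.drop(index=current.index[pos]).reset_index(drop=True)
    return HarmonizedSeries(sessions=current, target=target, removals=removals)


def harmonize_series(
    series: pd.DataFrame,
    target: int = TARGET_LENGTH_DEFAULT,
    tie_break: str = "small_gap_first",
) -> HarmonizedSeries:
    """Dispatch to padding or shrinking depending on the series length."""
    if len(series) > target:
        return shrink_series(series, target, tie_break)
    return pad_series(series, target)


def removals_to_records(patient_id: str, hs: HarmonizedSeries) -> list[dict]:
    return [
        {
            "patient_id": patient_id,
            "iteration": r.iteration,
            "date": r.date,
            "game_id": r.game_id,
        }
        for r in hs.removals
    ]
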