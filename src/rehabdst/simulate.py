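"""Seeded synthetic rehabilitation cohorts.

The generator emulates the statistical structure of per-round logs from a
planar rehabilitation robot driving seven serious games:

* each patient attends a variable number of therapy days and plays a variable
  subset of games per day, several rounds per game;
* each game reports only a subset of the kinematic features (controlling the
  cross-game "mutuality" of a feature);
* a latent motor-ability trajectory ``a_t`` in [0, 1] improves roughly
  linearly at a per-patient recovery rate and drives both the kinematic
  values and the discharge clinical scores (ARAT/FMA/MI);
* a persistence-biased therapist policy sets the three robot difficulty
  parameters day by day, escalating when latent performance is high;
* early rounds may run in "automode" (passive arm movement) with probability
  decaying geometrically over therapy days; such rounds carry no
  ability-related signal.

Ground-truth latents are returned so tests can check parameter recovery.
Nothing here aims at biomechanical realism: the quantities are plausible
scalars with the dependence structure the downstream pipeline assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

from .schema import (
    CLINICAL_SCALES,
    KINEMATIC_FEATURES,
    PARAMETER_LEVELS,
    ROBOT_PARAMETERS,
    SCALE_MAXIMA,
)

#: Features emitted by only 3 of 7 games (mutuality 3/7 < 70%); the ingest
#: filter is expected to drop them.
LOW_MUTUALITY_FEATURES: tuple[str, ...] = ("pathDeviation", "reactionTime")


def default_game_feature_masks(n_games: int = 7) -> dict[int, tuple[str, ...]]:
    """Per-game kinematic feature subsets.

    The first five canonical features appear in every game; each remaining
    canonical feature is absent from exactly one game (mutuality 6/7); two
    decoy features appear in three games only and should be filtered out.
    """
    masks: dict[int, list[str]] = {g: [] for g in range(1, n_games + 1)}
    for i, feat in enumerate(KINEMATIC_FEATURES):
        skip_game = (i % n_games) + 1 if i >= 5 else None
        for g in range(1, n_games + 1):
            if g != skip_game:
                masks[g].append(feat)
    for feat in LOW_MUTUALITY_FEATURES:
        for g in (1, 2, 3):
            if g <= n_games:
                masks[g].append(feat)
    return {g: tuple(v) for g, v in masks.items()}


class ConfigurationError(ValueError):
    """A SimConfig field is invalid; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for cohort generation (all seeded)."""

    n_patients: int = 60
    seed: int = 0
    days_range: tuple[int, int] = (10, 40)
    rounds_per_day_range: tuple[int, int] = (1, 3)  # rounds per game per day
    games_per_day_range: tuple[int, int] = (1, 4)  # distinct games per day
    n_games: int = 7
    game_feature_masks: dict[int, tuple[str, ...]] | None = None
    automode_prob_initial: float = 0.3
    automode_decay: float = 0.7  # geometric decay per therapy day
    recovery_rate_range: tuple[float, float] = (0.01, 0.06)
    initial_ability_range: tuple[float, float] = (0.05, 0.35)
    recovery_gap_range: tuple[float, float] = (0.1, 0.6)
    noise_sd: float = 0.05
    therapist_persistence: float = 0.9
    escalation_threshold: float = 0.5
    missing_prob: float = 0.03
    post_assessment_prob: float = 1.0  # <1 exercises the exclusion rule
    driver_feature: str | None = None  # single-feature signal injection
    start_date: str = "2024-01-06"

    def masks(self) -> dict[int, tuple[str, ...]]:
        if self.game_feature_masks is not None:
            return {g: tuple(v) for g, v in self.game_feature_masks.items()}
        return default_game_feature_masks(self.n_games)

    def validate(self) -> None:
        if self.n_games < 2:
            raise ConfigurationError("n_games must be >= 2")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not (1 <= self.days_range[0] <= self.days_range[1]):
            raise ConfigurationError("days_range must satisfy 1 <= min <= max")
        for name in (
            "automode_prob_initial",
            "automode_decay",
            "therapist_persistence",
            "missing_prob",
            "post_assessment_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        lo, hi = self.rounds_per_day_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("rounds_per_day_range must satisfy 1 <= min <= max")
        lo, hi = self.games_per_day_range
        if not (1 <= lo <= hi <= self.n_games):
            raise ConfigurationError(
                "games_per_day_range must satisfy 1 <= min <= max <= n_games"
            )
        lo, hi = self.recovery_rate_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("recovery_rate_range must satisfy 0 <= min <= max")
        if self.driver_feature is not None and self.driver_feature not in KINEMATIC_FEATURES:
            raise ConfigurationError(
                f"driver_feature must be one of the canonical kinematic features, "
                f"got {self.driver_feature!r}"
            )


@dataclass
class LatentState:
    """Ground-truth per-patient latents (for test oracles only)."""

    patient_id: str
    recovery_rate: float
    ability: list[float]  # per therapy day, in [0, 1]
    true_t0_frac: float  # pre-treatment score as fraction of scale max
    true_t1_frac: float  # discharge score fraction before observation noise


def therapist_policy(
    prev_levels: dict[str, str],
    latent_performance: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Next-session difficulty levels under a persistence-biased policy.

    With probability ``therapist_persistence`` the previous levels repeat
    unchanged (a single joint draw for the triple). Otherwise every parameter
    moves one level toward harder when ``latent_performance`` exceeds the
    escalation threshold, else one level toward easier, clamped at the ends
    of its level set.
    """
    for p, lvl in prev_levels.items():
        if lvl not in PARAMETER_LEVELS[p]:
            raise ValueError(f"invalid {p} level {lvl!r}")
    if rng.random() < config.therapist_persistence:
        return dict(prev_levels)
    step = 1 if latent_performance > config.escalation_threshold else -1
    nxt = {}
    for p in ROBOT_PARAMETERS:
        levels = PARAMETER_LEVELS[p]
        i = levels.index(prev_levels[p])
        nxt[p] = levels[min(max(i + step, 0), len(levels) - 1)]
    return nxt


def _base_values(features: list[str], rng: np.random.Generator) -> dict[str, float]:
    # Per-cohort baseline magnitude per feature; spread over two decades so
    # the per-game max normalization is doing real work.
    return {f: float(10.0 ** rng.uniform(-1.0, 1.0)) for f in features}


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[LatentState]]:
    """Generate (rounds, patients, latents) for one synthetic cohort.

    Returns
    -------
    rounds : DataFrame
        One row per played game round: ``patient_id, date, game_id,
        automode, stiffness, weight, viscosity`` plus one column per
        kinematic feature (NaN = not reported by the game / missing).
    patients : DataFrame
        ``patient_id, age, gender, latency_days`` plus ``{scale}_t0`` and
        ``{scale}_t1`` columns (t1 NaN when the discharge assessment is
        missing).
    latents : list of LatentState
        Ground truth for parameter-recovery tests; never consumed by the
        pipeline itself.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    masks = config.masks()
    all_features = sorted({f for fs in masks.values() for f in fs})
    base = _base_values(all_features, rng)
    start = _date.fromisoformat(config.start_date)

    round_rows: list[dict] = []
    patient_rows: list[dict] = []
    latents: list[LatentState] = []

    for pi in range(config.n_patients):
        pid = f"P{pi:03d}"
        n_days = int(rng.integers(config.days_range[0], config.days_range[1] + 1))
        rate = float(rng.uniform(*config.recovery_rate_range))
        a0 = float(rng.uniform(*config.initial_ability_range))
        ceiling = min(a0 + float(rng.uniform(*config.recovery_gap_range)), 0.95)
        # Therapy days: first day at offset 0, then gaps of 1-4 calendar days.
        gaps = rng.integers(1, 5, size=max(n_days - 1, 0))
        offsets = np.concatenate([[0], np.cumsum(gaps)]).astype(int)
        jitter = rng.normal(0.0, 0.02, size=n_days)
        # Exponential approach to a patient-specific plateau: recovery is
        # fastest early and levels off, and the plateau (not a global cap)
        # sets the discharge level.
        ability = np.clip(
            ceiling - (ceiling - a0) * np.exp(-rate * offsets) + jitter, 0.0, 1.0
        )

        levels = {
            "stiffness": str(rng.choice(["Low", "Mid"])),
            "weight": str(rng.choice(["Low", "Mid"])),
            "viscosity": str(rng.choice(["Low", "High"])),
        }
        for di, off in enumerate(offsets):
            if di > 0:
                levels = therapist_policy(levels, float(ability[di - 1]), config, rng)
            day_iso = (start + timedelta(days=int(off))).isoformat()
            p_auto = config.automode_prob_initial * config.automode_decay**di
            n_today = int(
                rng.integers(
                    config.games_per_day_range[0], config.games_per_day_range[1] + 1
                )
            )
            games_today = rng.choice(
                np.arange(1, config.n_games + 1), size=n_today, replace=False
            )
            for game in sorted(int(g) for g in games_today):
                n_rounds = int(
                    rng.integers(
                        config.rounds_per_day_range[0],
                        config.rounds_per_day_range[1] + 1,
                    )
                )
                for _ in range(n_rounds):
                    automode = bool(rng.random() < p_auto)
                    row = {
                        "patient_id": pid,
                        "date": day_iso,
                        "game_id": game,
                        "automode": int(automode),
                        **levels,
                    }
                    for feat in masks[game]:
                        if rng.random() < config.missing_prob:
                            continue  # leave missing
                        b = base[feat]
                        if automode:
                            # Passive movement: magnitude unrelated to ability.
                            val = b * 0.3 * math.exp(rng.normal(0.0, 0.3))
                        elif (
                            config.driver_feature is not None
                            and feat != config.driver_feature
                        ):
                            # Signal-injection mode: only the driver feature
                            # tracks ability; the rest is stationary noise.
                            val = b * math.exp(rng.normal(0.0, 0.3))
                        else:
                            val = (
                                b
                                * (0.3 + float(ability[di]))
                                * math.exp(rng.normal(0.0, max(config.noise_sd, 1e-9)))
                            )
                        row[feat] = val
                    round_rows.append(row)

        # Discharge scores: monotone in final ability, noisy observation.
        t0_frac = float(np.clip(0.7 * a0 + rng.normal(0.0, 0.03), 0.02, 0.9))
        t1_frac = float(np.clip(0.1 + 0.8 * ability[-1], 0.0, 1.0))
        has_post = bool(rng.random() < config.post_assessment_prob)
        prec = {
            "patient_id": pid,
            "age": float(np.clip(rng.normal(65.0, 12.0), 18.0, 95.0)),
            "gender": int(rng.random() < 0.5),
            "latency_days": float(np.round(np.exp(rng.normal(4.0, 0.6)))),
        }
        for scale in CLINICAL_SCALES:
            mx = SCALE_MAXIMA[scale]
            t0 = float(np.clip(round(t0_frac * mx), 0.0, mx))
            obs = t1_frac + rng.normal(0.0, config.noise_sd)
            t1 = float(np.clip(round(obs * mx), t0, mx))
            prec[f"{scale}_t0"] = t0
            prec[f"{scale}_t1"] = t1 if has_post else np.nan
        patient_rows.append(prec)
        latents.append(
            LatentState(
                patient_id=pid,
                recovery_rate=rate,
                ability=[float(a) for a in ability],
                true_t0_frac=t0_frac,
                true_t1_frac=t1_frac,
            )
        )

    columns = [
        "patient_id",
        "date",
        "game_id",
        "automode",
        "stiffness",
        "weight",
        "viscosity",
        *all_features,
    ]
    rounds = pd.DataFrame(round_rows).reindex(columns=columns)
    patients = pd.DataFrame(patient_rows)
    return rounds, patients, latents


def write_cohort(
    rounds: pd.DataFrame,
    patients: pd.DataFrame,
    latents: list[LatentState],
    outdir,
) -> None:
    """Write the CSV/JSON artifacts the ingest module reads."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rounds.to_csv(outdir / "rounds.csv", index=False)
    patients.to_csv(outdir / "patients.csv", index=False)
    payload = [
        {
            "patient_id": s.patient_id,
            "recovery_rate": s.recovery_rate,
            "ability": s.ability,
            "true_t0_frac": s.true_t0_frac,
            "true_t1_frac": s.true_t1_frac,
        }
        for s in latents
    ]
    (outdir / "latents.json").write_text(json.dumps(payload, indent=2))
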