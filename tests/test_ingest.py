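import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rehabdst import ingest
from rehabdst.schema import KINEMATIC_FEATURES


def _round(pid="P0", date="2024-01-01", game=1, automode=0, **kin):
    row = {
        "patient_id": pid, "date": date, "game_id": game, "automode": automode,
        "stiffness": "Mid", "weight": "Mid", "viscosity": "Low",
    }
    row.update(kin)
    return row


def test_automode_split_counts_and_conservation():
    rounds = pd.DataFrame(
        [_round(automode=0), _round(automode=1), _round(automode=1),
         _round(automode=0), _round(automode=0)]
    )
    active, counts = ingest.exclude_automode_rounds(rounds)
    assert len(active) == 3
    assert not active["automode"].astype(bool).any()
    assert counts.loc[0, "automode_count"] == 2
    assert len(active) + counts["automode_count"].sum() == len(rounds)


def test_automode_none_is_identity():
    rounds = pd.DataFrame([_round(), _round(game=2)])
    active, counts = ingest.exclude_automode_rounds(rounds)
    pd.testing.assert_frame_equal(active, rounds)
    assert counts.empty


def test_round_averaging_means_and_single_round_identity():
    rounds = pd.DataFrame(
        [
            _round(game=3, userVelocityAvg=0.2),
            _round(game=3, userVelocityAvg=0.4),
            _round(game=5, userVelocityAvg=0.7),
        ]
    )
    sessions = ingest.average_rounds_to_sessions(rounds)
    assert len(sessions) == 2
    s3 = sessions[sessions["game_id"] == 3].iloc[0]
    assert s3["userVelocityAvg"] == pytest.approx(0.3)
    assert s3["n_rounds"] == 2
    s5 = sessions[sessions["game_id"] == 5].iloc[0]
    assert s5["userVelocityAvg"] == pytest.approx(0.7)
    assert s5["n_rounds"] == 1


def test_same_day_games_become_two_sessions_same_date():
    rounds = pd.DataFrame([_round(game=1), _round(game=2)])
    sessions = ingest.average_rounds_to_sessions(rounds)
    assert len(sessions) == 2
    assert sessions["date"].nunique() == 1
    assert set(sessions["game_id"]) == {1, 2}
    assert (sessions["day"] == 0).all()


def test_sessions_chronological_with_stable_order():
    rounds = pd.DataFrame(
        [
            _round(date="2024-01-05", game=2),
            _round(date="2024-01-01", game=1),
            _round(date="2024-01-05", game=1),
        ]
    )
    sessions = ingest.average_rounds_to_sessions(rounds)
    assert list(sessions["day"]) == [0, 4, 4]
    # same-date sessions keep input order: game 2 appeared before game 1
    assert list(sessions["game_id"]) == [1, 2, 1]


def test_averaging_already_averaged_is_identity():
    rounds = pd.DataFrame(
        [_round(game=1, userVelocityAvg=0.5, workUserTotal=1.0),
         _round(date="2024-01-03", game=1, userVelocityAvg=0.7, workUserTotal=2.0)]
    )
    once = ingest.average_rounds_to_sessions(rounds)
    again = ingest.average_rounds_to_sessions(once.drop(columns=["day", "n_rounds"]).assign(automode=0))
    for col in ("userVelocityAvg", "workUserTotal"):
        assert list(once[col]) == list(again[col])


@pytest.mark.parametrize(
    "n_games_with_feature,retained", [(7, True), (6, True), (5, True), (4, False), (3, False)]
)
def test_mutuality_threshold_boundaries(n_games_with_feature, retained):
    """Strictly more than 70% of 7 games (>= 5) retains a feature."""
    rows = []
    for g in range(1, 8):
        kin = {"userVelocityAvg": 1.0}
        if g <= n_games_with_feature:
            kin["calories"] = 2.0
        rows.append(_round(date=f"2024-01-{g:02d}", game=g, **kin))
    sessions = ingest.average_rounds_to_sessions(pd.DataFrame(rows))
    got = ingest.filter_features_by_mutuality(sessions, n_games=7)
    assert ("calories" in got) == retained
    assert "userVelocityAvg" in got


@settings(deadline=None, max_examples=50)
@given(st.lists(st.booleans(), min_size=7, max_size=7), st.integers(0, 2**31 - 1))
def test_mutuality_matches_brute_force(mask, seed):
    """Observational mutuality equals a brute-force set-membership count."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(1, 8):
        kin = {"userVelocityAvg": float(rng.uniform(0.1, 1.0))}
        if mask[g - 1]:
            kin["calories"] = float(rng.uniform(0.1, 1.0))
        rows.append(_round(date=f"2024-01-{g:02d}", game=g, **kin))
    sessions = ingest.average_rounds_to_sessions(pd.DataFrame(rows))
    got = ingest.filter_features_by_mutuality(sessions, n_games=7)
    assert ("calories" in got) == (sum(mask) / 7 > 0.70)


def test_mutuality_empty_sessions_error():
    with pytest.raises(ValueError, match="empty"):
        ingest.filter_features_by_mutuality(pd.DataFrame(), n_games=7)


def test_fill_uses_date_mean_then_front_fill():
    rounds = pd.DataFrame(
        [
            _round(date="2024-01-01", game=1, calories=0.2),
            _round(date="2024-01-01", game=2),  # missing -> date mean 0.3
            _round(date="2024-01-01", game=3, calories=0.4),
            _round(date="2024-01-04", game=1, calories=0.5),
            _round(date="2024-01-06", game=2),  # sole session -> front-fill 0.5
        ]
    )
    sessions = ingest.average_rounds_to_sessions(rounds)
    filled = ingest.fill_missing_values(sessions, ["calories"])
    assert filled["calories"].notna().all()
    day0 = filled[(filled["day"] == 0) & (filled["game_id"] == 2)]["calories"].iloc[0]
    assert day0 == pytest.approx(0.3)
    day5 = filled[filled["day"] == 5]["calories"].iloc[0]
    assert day5 == pytest.approx(0.5)


def test_fill_complete_input_is_identity():
    rounds = pd.DataFrame([_round(calories=1.0), _round(date="2024-01-02", calories=2.0)])
    sessions = ingest.average_rounds_to_sessions(rounds)
    filled = ingest.fill_missing_values(sessions, ["calories"])
    pd.testing.assert_frame_equal(filled, sessions)


def _patients(rows):
    base = {"age": 60.0, "gender": 1, "latency_days": 30.0,
            "arat_t0": 10, "fma_t0": 20, "mi_t0": 30,
            "arat_t1": 20, "fma_t1": 30, "mi_t1": 40}
    return pd.DataFrame([{**base, **r} for r in rows])


def _sessions_with_dates(pid, n_dates):
    return [
        _round(pid=pid, date=f"2024-01-{d + 1:02d}", game=1, userVelocityAvg=1.0)
        for d in range(n_dates)
    ]


def test_exclusions_attendance_and_post_assessment():
    rounds = pd.DataFrame(
        _sessions_with_dates("A", 9)  # too few attendances
        + _sessions_with_dates("B", 12)  # missing T1
        + _sessions_with_dates("C", 10)  # retained (boundary inclusive)
        + _sessions_with_dates("D", 5)  # fails both -> no_post takes precedence
    )
    sessions = ingest.average_rounds_to_sessions(rounds)
    patients = _patients(
        [
            {"patient_id": "A"},
            {"patient_id": "B", "fma_t1": np.nan},
            {"patient_id": "C"},
            {"patient_id": "D", "arat_t1": np.nan},
        ]
    )
    retained, kept_sessions, report = ingest.apply_patient_exclusions(patients, sessions)
    assert list(retained["patient_id"]) == ["C"]
    assert report.n_excluded_no_post_assessment == 2
    assert report.n_excluded_too_few_attendances == 1
    assert report.reasons == {
        "A": "too_few_attendances",
        "B": "no_post_assessment",
        "D": "no_post_assessment",
    }
    assert report.n_retained + 3 == report.n_input_patients
    assert set(kept_sessions["patient_id"]) == {"C"}


def test_round_conservation_on_synthetic_cohort(small_cohort):
    """Every generated round lands in exactly one session average or in the
    automode counts."""
    _, rounds, _, _ = small_cohort
    active, counts = ingest.exclude_automode_rounds(rounds)
    sessions = ingest.average_rounds_to_sessions(active)
    assert sessions["n_rounds"].sum() + counts["automode_count"].sum() == len(rounds)
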