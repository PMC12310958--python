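import numpy as np
import pandas as pd
import pytest

from rehabdst.ingest import filter_features_by_mutuality, exclude_automode_rounds, average_rounds_to_sessions
from rehabdst.schema import KINEMATIC_FEATURES, SCALE_MAXIMA
from rehabdst.simulate import (
    ConfigurationError,
    SimConfig,
    generate_cohort,
    therapist_policy,
)


def test_same_seed_bitwise_identical():
    cfg = SimConfig(n_patients=6, seed=1)
    r1, p1, l1 = generate_cohort(cfg)
    r2, p2, l2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(r1, r2)
    pd.testing.assert_frame_equal(p1, p2)
    assert [s.ability for s in l1] == [s.ability for s in l2]


def test_scores_within_scale_bounds(small_cohort):
    _, _, patients, _ = small_cohort
    for scale, mx in SCALE_MAXIMA.items():
        assert patients[f"{scale}_t0"].between(0, mx).all()
        t1 = patients[f"{scale}_t1"].dropna()
        assert t1.between(0, mx).all()


def test_kinematics_non_negative(small_cohort):
    _, rounds, _, _ = small_cohort
    feats = [c for c in rounds.columns if c not in
             ("patient_id", "date", "game_id", "automode", "stiffness", "weight", "viscosity")]
    assert (rounds[feats].fillna(0) >= 0).all().all()


def test_rounds_respect_game_feature_masks(small_cohort):
    cfg, rounds, _, _ = small_cohort
    masks = cfg.masks()
    for game, grp in rounds.groupby("game_id"):
        outside = [f for f in rounds.columns if f in set().union(*masks.values()) - set(masks[game])]
        assert grp[outside].isna().all().all()


def test_days_within_configured_range(small_cohort):
    cfg, rounds, _, _ = small_cohort
    for _, grp in rounds.groupby("patient_id"):
        n_days = grp["date"].nunique()
        assert cfg.days_range[0] <= n_days <= cfg.days_range[1]


def test_full_persistence_keeps_levels_constant():
    cfg = SimConfig(n_patients=4, seed=3, therapist_persistence=1.0, noise_sd=0.0)
    rounds, _, _ = generate_cohort(cfg)
    for _, grp in rounds.groupby("patient_id"):
        for p in ("stiffness", "weight", "viscosity"):
            assert grp[p].nunique() == 1


def test_invalid_config_names_field():
    with pytest.raises(ConfigurationError, match="noise_sd"):
        SimConfig(noise_sd=-1).validate()
    with pytest.raises(ConfigurationError, match="n_games"):
        SimConfig(n_games=1).validate()
    with pytest.raises(ConfigurationError, match="therapist_persistence"):
        SimConfig(therapist_persistence=1.5).validate()
    with pytest.raises(ConfigurationError, match="driver_feature"):
        SimConfig(driver_feature="not_a_feature").validate()


def test_policy_persistence_and_clamping():
    cfg = SimConfig(therapist_persistence=1.0)
    rng = np.random.default_rng(0)
    prev = {"stiffness": "Mid", "weight": "Low", "viscosity": "High"}
    assert therapist_policy(prev, 0.9, cfg, rng) == prev

    cfg = SimConfig(therapist_persistence=0.0, escalation_threshold=0.5)
    harder = therapist_policy(
        {"stiffness": "High", "weight": "Mid", "viscosity": "High"}, 0.9, cfg, rng
    )
    assert harder == {"stiffness": "High", "weight": "High", "viscosity": "High"}
    easier = therapist_policy(
        {"stiffness": "Low", "weight": "Mid", "viscosity": "Low"}, 0.1, cfg, rng
    )
    assert easier == {"stiffness": "Low", "weight": "Low", "viscosity": "Low"}


def test_policy_monte_carlo_repeat_fraction():
    """Over many draws the joint repeat fraction matches the configured
    persistence (binomial check at 0.8 +- 0.02)."""
    cfg = SimConfig(therapist_persistence=0.8, escalation_threshold=0.5)
    rng = np.random.default_rng(123)
    prev = {"stiffness": "Mid", "weight": "Mid", "viscosity": "Low"}
    n = 10_000
    repeats = sum(
        therapist_policy(prev, 0.9, cfg, rng) == prev for _ in range(n)
    )
    assert abs(repeats / n - 0.8) < 0.02


def test_mutuality_control_is_exact():
    """A feature placed in k of 7 game masks yields an ingest mutuality
    estimate of exactly k/7."""
    masks = {g: tuple(KINEMATIC_FEATURES) for g in range(1, 8)}
    masks = {
        g: tuple(f for f in fs if not (f == "calories" and g > 4))
        for g, fs in masks.items()
    }  # calories in games 1..4 only: 4/7 < 0.7
    cfg = SimConfig(n_patients=4, seed=5, game_feature_masks=masks, missing_prob=0.0)
    rounds, _, _ = generate_cohort(cfg)
    active, _ = exclude_automode_rounds(rounds)
    sessions = average_rounds_to_sessions(active)
    retained = filter_features_by_mutuality(sessions, masks, n_games=7)
    assert "calories" not in retained
    assert set(retained) == set(KINEMATIC_FEATURES) - {"calories"}


def test_recovery_rate_drives_score_gain():
    """With low noise, per-patient score gain correlates positively with the
    true latent recovery rate expressed through the plateau dynamics."""
    cfg = SimConfig(n_patients=40, seed=8, noise_sd=0.01)
    _, patients, latents = generate_cohort(cfg)
    gain = (patients["fma_t1"] - patients["fma_t0"]).to_numpy()
    true_gain = np.array([s.true_t1_frac - 0.7 * s.ability[0] for s in latents])
    assert np.corrcoef(gain, true_gain)[0, 1] > 0.5
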