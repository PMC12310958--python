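import numpy as np
import pytest

from rehabdst import models, tensors
from rehabdst.schema import FeatureSchema


def test_fold_plan_balanced_78_patients():
    ids = [f"P{i:03d}" for i in range(78)]
    plan = models.make_cv_folds(ids, 5, seed=42)
    sizes = sorted(len(f) for f in plan.folds)
    assert sizes == [15, 15, 16, 16, 16]
    seen = [pid for f in plan.folds for pid in f]
    assert sorted(seen) == sorted(ids)  # partition: no patient twice


def test_fold_plan_deterministic_and_split_disjoint():
    ids = [f"P{i}" for i in range(60)]
    a = models.make_cv_folds(ids, 5, seed=7)
    b = models.make_cv_folds(ids, 5, seed=7)
    assert a == b
    assert all(len(f) == 12 for f in a.folds)
    train, test = a.split(2)
    assert not set(train) & set(test)
    assert len(train) + len(test) == 60


def test_fold_plan_errors():
    with pytest.raises(ValueError):
        models.make_cv_folds(["a", "b", "c"], 1, 0)
    with pytest.raises(ValueError):
        models.make_cv_folds(["a", "b"], 3, 0)


def test_outcome_model_forward_contract():
    model = models.OutcomeModel(models.OutcomeModelConfig(seed=0))
    zeros = tensors.CohortTensor(
        np.zeros((2, 64, 36)), np.ones((2, 64), dtype=bool), np.zeros((2, 3)),
        np.zeros((2, 64, 3), dtype=int), ["A", "B"], FeatureSchema(),
    )
    pred = model.predict_normalized(zeros)
    assert pred.shape == (2, 64, 3)
    assert np.isfinite(pred).all()
    assert pred.min() >= 0.0 and pred.max() <= 1.0
    denorm = model.predict(zeros)
    assert denorm[..., 0].max() <= 57 and denorm[..., 1].max() <= 66 and denorm[..., 2].max() <= 100


def test_outcome_architecture_parameter_count_stable():
    a = models.OutcomeModel(models.OutcomeModelConfig(seed=1))
    b = models.OutcomeModel(models.OutcomeModelConfig(seed=99))
    assert a.n_parameters == b.n_parameters
    # 6 recurrent layers plus the 3-unit per-step head
    n_lstm = sum(1 for l in a.net.layers if hasattr(l, "Wx"))
    assert n_lstm == 6


def _toy_tensor(P=6, T=10, seed=0):
    rng = np.random.default_rng(seed)
    schema = FeatureSchema()
    values = np.zeros((P, T, 36))
    mask = np.ones((P, T), dtype=bool)
    driver = rng.uniform(size=(P, 1))
    values[:, :, 3] = driver  # one kinematic column carries the signal
    values[:, :, 4:19] = rng.uniform(size=(P, T, 15)) * 0.1
    labels = np.repeat(driver, 3, axis=1)
    classes = np.zeros((P, T, 3), dtype=int)
    return tensors.CohortTensor(values, mask, labels, classes, [f"P{i}" for i in range(P)], schema)


def test_outcome_training_learns_and_is_seed_deterministic():
    train = _toy_tensor()
    cfg = models.OutcomeModelConfig(max_epochs=15, patience=15, seed=3,
                                    validation_fraction=0.0)
    m1 = models.OutcomeModel(cfg).fit(train)
    losses = [h["train_loss"] for h in m1.history if "epoch" in h]
    assert losses[-1] < losses[0]
    m2 = models.OutcomeModel(cfg).fit(train)
    for w1, w2 in zip(m1.net.get_weights(), m2.net.get_weights()):
        assert np.array_equal(w1, w2)


def test_outcome_zero_learning_rate_leaves_weights_unchanged():
    train = _toy_tensor()
    cfg = models.OutcomeModelConfig(
        learning_rate=0.0, fallback_learning_rate=0.0,
        max_epochs=3, patience=5, seed=4, dropout_rate=0.0,
    )
    model = models.OutcomeModel(cfg)
    before = model.net.get_weights()
    model.fit(train)
    for w0, w1 in zip(before, model.net.get_weights()):
        assert np.array_equal(w0, w1)


def test_difficulty_presets_match_parameter_table():
    s = models.DIFFICULTY_PRESETS["stiffness"]
    assert (s.n_recurrent_layers, s.units_per_layer, s.lookback, s.dropout_rate) == (2, 64, 3, 0.1)
    w = models.DIFFICULTY_PRESETS["weight"]
    assert (w.n_recurrent_layers, w.units_per_layer, w.lookback, w.dropout_rate) == (1, 32, 3, 0.2)
    v = models.DIFFICULTY_PRESETS["viscosity"]
    assert (v.n_recurrent_layers, v.units_per_layer, v.lookback, v.dropout_rate) == (1, 64, 5, 0.2)
    assert s.n_classes == 3 and w.n_classes == 3 and v.n_classes == 2
    assert s.batch_size == 256


def test_difficulty_probabilities_and_argmax_tie_break():
    dm = models.build_difficulty_model("stiffness")
    rng = np.random.default_rng(0)
    windows = rng.uniform(size=(10, 3, 36))
    proba = dm.predict_proba(windows)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    # exact tie -> lower (easier) class index
    assert np.argmax(np.array([0.4, 0.4, 0.2])) == 0
    p, level = dm.recommend(windows[0])
    assert level in ("Low", "Mid", "High")
    with pytest.raises(ValueError, match="windows of length"):
        dm.predict_proba(rng.uniform(size=(4, 5, 36)))


def test_difficulty_model_learns_copy_rule():
    """Windows whose last step encodes the class are perfectly learnable."""
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 3, size=400)
    windows = rng.uniform(size=(400, 3, 36)) * 0.05
    windows[:, -1, 19] = (labels + 1) / 3.0  # stiffness column
    cfg = models.DifficultyModelConfig(
        parameter="stiffness", n_recurrent_layers=1, units_per_layer=16,
        lookback=3, dropout_rate=0.0, max_epochs=500, patience=500, seed=0,
        validation_fraction=0.0,
    )
    dm = models.DifficultyModel(cfg).fit(windows, labels)
    acc = (dm.predict_classes(windows) == labels).mean()
    assert acc > 0.97


def test_rf_hyperparameters_and_determinism():
    cfg = models.RFConfig(seed=0)
    reg = models.RFOutcomeBaseline(cfg)
    params = reg.model.get_params()
    assert params["n_estimators"] == 300
    assert params["max_depth"] == 10
    assert params["min_samples_split"] == 5
    assert params["min_samples_leaf"] == 20
    clf = models.RFDifficultyBaseline("stiffness", cfg)
    cp = clf.model.get_params()
    assert (cp["n_estimators"], cp["max_depth"], cp["min_samples_split"],
            cp["min_samples_leaf"]) == (350, 15, 5, 5)

    train = _toy_tensor()
    reg.fit(train)
    assert all(est.get_depth() <= 10 for est in reg.model.estimators_)
    p1 = reg.predict_normalized(train)
    p2 = models.RFOutcomeBaseline(cfg).fit(train).predict_normalized(train)
    assert np.array_equal(p1, p2)


def test_model_save_load_round_trip(tmp_path):
    train = _toy_tensor()
    cfg = models.OutcomeModelConfig(max_epochs=2, patience=5, seed=0,
                                    validation_fraction=0.0)
    m = models.OutcomeModel(cfg).fit(train)
    models.save_outcome_model(m, tmp_path / "om")
    loaded = models.load_outcome_model(tmp_path / "om")
    assert np.array_equal(loaded.predict_normalized(train), m.predict_normalized(train))

    dmcfg = models.DifficultyModelConfig(
        parameter="viscosity", n_recurrent_layers=1, units_per_layer=8,
        lookback=2, dropout_rate=0.0, max_epochs=2, patience=5, seed=0,
    )
    rng = np.random.default_rng(1)
    w = rng.uniform(size=(30, 2, 36))
    y = rng.integers(0, 2, size=30)
    dm = models.DifficultyModel(dmcfg).fit(w, y)
    models.save_difficulty_model(dm, tmp_path / "dm")
    dl = models.load_difficulty_model(tmp_path / "dm")
    assert np.array_equal(dl.predict_proba(w), dm.predict_proba(w))
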