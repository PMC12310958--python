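import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import accuracy_score, f1_score, mean_absolute_error, mean_squared_error

from rehabdst import evaluation as ev


def test_rmse_mae_hand_values():
    assert ev.rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert ev.mae([1, 2, 3], [1, 2, 3]) == 0.0
    assert ev.rmse([0, 0], [1, 1]) == pytest.approx(1.0)
    assert ev.mae([0, 0], [1, 1]) == pytest.approx(1.0)
    assert ev.rmse([1, 2, 3], [2, 2, 4]) == pytest.approx(np.sqrt(2 / 3))
    assert ev.mae([1, 2, 3], [2, 2, 4]) == pytest.approx(2 / 3)


def test_metric_input_validation():
    with pytest.raises(ValueError):
        ev.rmse([1, 2], [1])
    with pytest.raises(ValueError):
        ev.mae([], [])


def test_metrics_match_sklearn_on_1000_random_vectors():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = int(rng.integers(1, 12))
        y = rng.normal(size=n)
        yh = rng.normal(size=n)
        assert abs(ev.rmse(y, yh) - np.sqrt(mean_squared_error(y, yh))) < 1e-12
        assert abs(ev.mae(y, yh) - mean_absolute_error(y, yh)) < 1e-12


def test_confusion_counts_and_oa():
    counts = ev.ConfusionCounts(tp=3, tn=5, fp=1, fn=1)
    assert ev.overall_accuracy(counts) == pytest.approx(0.8)
    assert counts.precision == pytest.approx(0.75)
    assert counts.recall == pytest.approx(0.75)
    assert ev.f1(counts) == pytest.approx(0.75)


def test_f1_degenerate_zero_with_warning():
    counts = ev.ConfusionCounts(tp=0, tn=5, fp=0, fn=0)
    with pytest.warns(UserWarning):
        assert ev.f1(counts) == 0.0


def test_perfect_classifier_is_one():
    y = np.array([0, 1, 2, 1, 0])
    assert ev.multiclass_accuracy(y, y) == 1.0
    assert ev.multiclass_f1(y, y) == 1.0


def test_multiclass_metrics_match_sklearn():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(2, 40))
        y = rng.integers(0, 3, size=n)
        yh = rng.integers(0, 3, size=n)
        assert abs(ev.multiclass_accuracy(y, yh) - accuracy_score(y, yh)) < 1e-12
        labels = np.unique(np.concatenate([y, yh]))
        assert abs(
            ev.multiclass_f1(y, yh, "weighted")
            - f1_score(y, yh, labels=labels, average="weighted", zero_division=0)
        ) < 1e-12
        assert abs(
            ev.multiclass_f1(y, yh, "macro")
            - f1_score(y, yh, labels=labels, average="macro", zero_division=0)
        ) < 1e-12


def test_percentage_difference_signs():
    res = ev.percentage_difference(57, 45.6, 57)
    assert res.pd == pytest.approx(0.2)  # under-prediction -> positive
    assert ev.percentage_difference(40, 40, 100).pd == 0.0
    assert ev.percentage_difference(40, 50, 100).pd == pytest.approx(-0.10)
    with pytest.raises(ValueError):
        ev.percentage_difference(1, 1, 0)


@pytest.mark.parametrize(
    "pd_value,group",
    [
        (-0.10, "within"),
        (0.10, "within"),
        (0.0, "within"),
        (0.25, "under_predicted"),
        (-0.2, "over_predicted"),
        (0.1000001, "under_predicted"),
    ],
)
def test_mcid_groups_with_inclusive_boundaries(pd_value, group):
    assert ev.assign_mcid_group(pd_value) == group


def test_mcid_requires_finite():
    with pytest.raises(ValueError):
        ev.assign_mcid_group(float("nan"))


def test_aggregate_session_errors_pooled_matches_brute_force():
    """Three-patient toy: errors pool over steps, not per-patient means."""
    rng = np.random.default_rng(0)
    P, T = 3, 5
    preds = rng.uniform(size=(P, T, 3))
    labels = rng.uniform(size=(P, 3))
    mask = np.ones((P, T), dtype=bool)
    mask[1, 3:] = False
    preds[~mask] = 0.0
    got = ev.aggregate_session_errors(preds, labels, mask, ["A", "B", "C"])
    for si, scale in enumerate(("arat", "fma", "mi")):
        errs = []
        for p in range(P):
            for t in range(T):
                if mask[p, t]:
                    errs.append(labels[p, si] - preds[p, t, si])
        errs = np.array(errs)
        assert got.rmse[scale] == pytest.approx(np.sqrt(np.mean(errs**2)), abs=1e-12)
        assert got.mae[scale] == pytest.approx(np.mean(np.abs(errs)), abs=1e-12)
    # pooled and per-patient-then-average genuinely differ here
    per_patient = [
        np.sqrt(np.mean((labels[p, 0] - preds[p, mask[p], 0]) ** 2)) for p in range(P)
    ]
    assert got.rmse["arat"] != pytest.approx(np.mean(per_patient))


def test_aggregate_empty_fold_errors():
    with pytest.raises(ValueError, match="empty"):
        ev.aggregate_session_errors(
            np.zeros((1, 4, 3)), np.zeros((1, 3)), np.zeros((1, 4), dtype=bool), ["A"]
        )


def test_mcid_partition_is_exhaustive(fold_tensors):
    train, test, _ = fold_tensors
    preds = np.clip(np.broadcast_to(train.labels.mean(0), test.values.shape[:2] + (3,)), 0, 1)
    got = ev.aggregate_session_errors(preds, test.labels, test.mask, test.patient_ids)
    for scale in ("arat", "fma", "mi"):
        assert set(got.patient_mcid[scale]) == set(test.patient_ids)
        assert all(
            g in ("within", "over_predicted", "under_predicted")
            for g in got.patient_mcid[scale].values()
        )


def test_permutation_importance_sums_to_one_and_finds_driver():
    rng = np.random.default_rng(7)
    X = rng.uniform(size=(60, 4, 5))

    def metric(Xp):  # model that only uses feature 2
        return float(np.mean((Xp[:, :, 2] - X[:, :, 2]) ** 2))

    imp = ev.permutation_importance(metric, X, 5, n_repeats=5, seed=1)
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.argmax(imp) == 2
    assert imp[[0, 1, 3, 4]] == pytest.approx(0.0)


def test_permutation_invariant_model_has_zero_importance():
    rng = np.random.default_rng(8)
    X = rng.uniform(size=(30, 3, 4))
    imp = ev.permutation_importance(lambda Xp: 1.0, X, 4, n_repeats=3, seed=0)
    assert (imp == 0).all()


def test_compare_models_ties_dominance_and_symmetry():
    with pytest.warns(UserWarning, match="tied"):
        assert ev.compare_models([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0
    a = list(np.linspace(0.1, 0.5, 10))
    b = [x + 0.05 for x in a]
    p = ev.compare_models(a, b)
    # smallest attainable two-sided signed-rank p for n=10 is 2/2^10
    assert p == pytest.approx(2 / 1024, rel=1e-6)
    assert ev.compare_models(b, a) == pytest.approx(p)
    with pytest.raises(ValueError):
        ev.compare_models([1, 2], [2, 3])


@settings(deadline=None, max_examples=100)
@given(
    st.lists(st.floats(-100, 100), min_size=1, max_size=20),
    st.integers(0, 2**31 - 1),
)
def test_rmse_dominates_mae(values, seed):
    rng = np.random.default_rng(seed)
    y = np.array(values)
    yh = y + rng.normal(size=y.size)
    assert ev.rmse(y, yh) >= ev.mae(y, yh) - 1e-12
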