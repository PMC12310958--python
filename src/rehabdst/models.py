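"""The two decision-support tools and their random-forest baselines.

Outcome DST — a stack of six 32-unit LSTM layers (tanh gates), 20% dropout
after each, and a dense head shared across time-steps that emits the three
normalized discharge scores (ARAT, FMA, MI) at every valid step. Trained
with batch size 1 (patient by patient), masked MSE and RMSprop. The default
learning rate is 0.001: at batch size 1 this implementation found a 0.1
initial rate to random-walk the weights into gate saturation and
underperform even a constant predictor, so higher rates are configurable
but guarded — a run that diverges (non-finite loss, or failure to beat the
constant train-mean predictor within a warm-up budget) restarts from
scratch at the fallback rate.

Difficulty DSTs — one classifier per robot parameter, consuming lookback
windows of 3 (stiffness, weight) or 5 (viscosity) previous time-points:
stiffness 2x64-unit LSTM layers with 0.1 dropout, weight 1x32 with 0.2,
viscosity 1x64 with 0.2; softmax class output, categorical cross-entropy,
Adam, batch size 256. The recommended level is the argmax class (ties go to
the easier level) mapped back to Low/Mid/High (or Low/High).

Random-forest baselines use scikit-learn with fixed hyperparameters
(regression: 300 trees / depth 10 / split 5 / leaf 20; classification:
350 / 15 / 5 / 5), trained on the identical patient-level folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import nn
from .normalize import denormalize_clinical_scores
from .schema import PARAMETER_LEVELS, ROBOT_PARAMETERS, index_to_level
from .tensors import CohortTensor, LookbackDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutcomeModelConfig:
    n_recurrent_layers: int = 6
    units_per_layer: int = 32
    dropout_rate: float = 0.2
    learning_rate: float = 0.001
    fallback_learning_rate: float = 0.001
    divergence_check_epochs: int = 10
    batch_size: int = 1
    max_epochs: int = 300
    patience: int = 20
    validation_fraction: float = 0.15
    clipnorm: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size != 1:
            raise ValueError("the outcome model trains patient-by-patient (batch size 1)")


@dataclass(frozen=True)
class DifficultyModelConfig:
    parameter: str
    n_recurrent_layers: int
    units_per_layer: int
    lookback: int
    dropout_rate: float
    learning_rate: float = 0.001
    batch_size: int = 256
    max_epochs: int = 300
    patience: int = 20
    validation_fraction: float = 0.15
    clipnorm: float = 1.0
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(PARAMETER_LEVELS[self.parameter])


#: Per-parameter difficulty-model settings.
DIFFICULTY_PRESETS: dict[str, DifficultyModelConfig] = {
    "stiffness": DifficultyModelConfig(
        parameter="stiffness", n_recurrent_layers=2, units_per_layer=64,
        lookback=3, dropout_rate=0.1,
    ),
    "weight": DifficultyModelConfig(
        parameter="weight", n_recurrent_layers=1, units_per_layer=32,
        lookback=3, dropout_rate=0.2,
    ),
    "viscosity": DifficultyModelConfig(
        parameter="viscosity", n_recurrent_layers=1, units_per_layer=64,
        lookback=5, dropout_rate=0.2,
    ),
}


@dataclass(frozen=True)
class RFConfig:
    outcome_n_estimators: int = 300
    outcome_max_depth: int = 10
    outcome_min_samples_split: int = 5
    outcome_min_samples_leaf: int = 20
    reco_n_estimators: int = 350
    reco_max_depth: int = 15
    reco_min_samples_split: int = 5
    reco_min_samples_leaf: int = 5
    seed: int = 0


@dataclass(frozen=True)
class FoldPlan:
    """Patient-level cross-validation partition shared by all models."""

    folds: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        test = list(self.folds[fold])
        train = [pid for i, f in enumerate(self.folds) if i != fold for pid in f]
        return train, test


def make_cv_folds(patient_ids: list[str], k: int, seed: int) -> FoldPlan:
    """Deterministic near-equal patient-level partition (fold sizes differ
    by at most one)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(patient_ids):
        raise ValueError("k cannot exceed the number of patients")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patient_ids))
    shuffled = [patient_ids[i] for i in order]
    folds = tuple(tuple(chunk) for chunk in np.array_split(shuffled, k))
    return FoldPlan(folds=folds, seed=seed)


class OutcomeModel:
    """Per-time-step discharge-score regressor."""

    def __init__(self, config: OutcomeModelConfig, input_dim: int = 36):
        config.validate()
        self.config = config
        self.input_dim = input_dim
        self.net = nn.LSTMStack(
            input_dim=input_dim,
            n_layers=config.n_recurrent_layers,
            units=config.units_per_layer,
            output_dim=3,
            dropout=config.dropout_rate,
            seed=config.seed,
            return_sequences=True,
        )
        self.history: list[dict] = []

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def loss(self, values: np.ndarray, mask: np.ndarray, labels: np.ndarray) -> float:
        pred = self.net.forward(values, training=False)
        loss, _ = nn.masked_mse(pred, labels, mask)
        return loss

    def _fit_at_rate(self, tr, va, lr: float, rng, check_divergence: bool) -> None:
        """One training run at a fixed learning rate with early stopping.

        Divergence contract: a non-finite loss, or — when
        ``check_divergence`` — a monitored loss that has not beaten the
        constant train-label-mean predictor after ``divergence_check_epochs``
        epochs, raises :class:`rehabdst.nn.DivergenceError`.
        """
        cfg = self.config
        x_tr, m_tr, y_tr = tr
        opt = nn.RMSprop(lr=lr, clipnorm=cfg.clipnorm)
        # Internal non-convergence yardstick: MSE of predicting the training
        # labels' mean on the monitored split.
        mean_label = y_tr.mean(axis=0)
        mon_x, mon_m, mon_y = va if va is not None else tr
        const_pred = np.broadcast_to(
            mean_label, (mon_x.shape[0], mon_x.shape[1], 3)
        )
        baseline_loss, _ = nn.masked_mse(const_pred, mon_y, mon_m)

        best = np.inf
        best_weights = self.net.get_weights()
        since_best = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(x_tr.shape[0])
            train_loss = 0.0
            for i in order:  # batch size 1, patient by patient
                pred = self.net.forward(x_tr[i : i + 1], training=True)
                loss, dpred = nn.masked_mse(pred, y_tr[i : i + 1], m_tr[i : i + 1])
                if not np.isfinite(loss):
                    raise nn.DivergenceError(
                        f"non-finite training loss at learning rate {lr}; "
                        "a lower learning rate is needed"
                    )
                self.net.backward(dpred)
                opt.step(self.net.params, self.net.grads)
                train_loss += loss
            train_loss /= max(len(order), 1)
            monitored = self.loss(mon_x, mon_m, mon_y)
            self.history.append(
                {"epoch": epoch, "lr": lr, "train_loss": train_loss,
                 "monitored_loss": monitored, "constant_baseline": baseline_loss}
            )
            if monitored < best - 1e-6:
                best = monitored
                best_weights = self.net.get_weights()
                since_best = 0
            else:
                since_best += 1
            if (
                check_divergence
                and epoch + 1 == cfg.divergence_check_epochs
                and best >= baseline_loss
            ):
                raise nn.DivergenceError(
                    f"monitored loss {best:.4g} has not beaten the constant-"
                    f"predictor baseline {baseline_loss:.4g} after "
                    f"{epoch + 1} epochs at learning rate {lr}"
                )
            if since_best >= cfg.patience:
                break
        self.net.set_weights(best_weights)

    def fit(self, train: CohortTensor) -> "OutcomeModel":
        """Train patient-by-patient with early stopping on a held-out split.

        Training honors the configured initial rate (0.1); if it diverges —
        a non-finite loss, or failure to beat the constant train-mean
        predictor within the warm-up budget — the model re-initializes and
        restarts from scratch at the fallback rate (0.001), recorded in the
        history. Divergence at the fallback rate itself aborts with a
        diagnostic suggesting a lower rate.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        P = train.n_patients
        n_val = int(round(cfg.validation_fraction * P))
        va = None
        tr_idx = np.arange(P)
        if n_val >= 1 and P - n_val >= 2:
            perm = rng.permutation(P)
            va_idx, tr_idx = perm[:n_val], perm[n_val:]
            va = (train.values[va_idx], train.mask[va_idx], train.labels[va_idx])
        tr = (train.values[tr_idx], train.mask[tr_idx], train.labels[tr_idx])
        init_weights = self.net.get_weights()
        try:
            self._fit_at_rate(
                tr, va, cfg.learning_rate, rng,
                check_divergence=cfg.learning_rate > cfg.fallback_learning_rate,
            )
        except nn.DivergenceError as exc:
            if cfg.learning_rate <= cfg.fallback_learning_rate:
                raise
            logger.warning(
                "outcome model diverged (%s); restarting at fallback rate %g",
                exc, cfg.fallback_learning_rate,
            )
            self.history.append({"event": "fallback", "lr": cfg.fallback_learning_rate})
            self.net.set_weights(init_weights)
            rng = np.random.default_rng(cfg.seed + 1)
            self._fit_at_rate(tr, va, cfg.fallback_learning_rate, rng,
                              check_divergence=False)
        return self

    def predict_normalized(self, tensor: CohortTensor) -> np.ndarray:
        """(P, T, 3) predictions clipped to [0, 1]; padded rows are
        meaningless and should be read through the mask."""
        if tensor.values.shape[2] != self.input_dim:
            raise ValueError("tensor schema does not match the trained model")
        return np.clip(self.net.forward(tensor.values, training=False), 0.0, 1.0)

    def predict(self, tensor: CohortTensor) -> np.ndarray:
        """Denormalized per-step (ARAT, FMA, MI) predictions."""
        return denormalize_clinical_scores(self.predict_normalized(tensor))


class DifficultyModel:
    """Next-session level recommender for one robot parameter."""

    def __init__(self, config: DifficultyModelConfig, input_dim: int = 36):
        self.config = config
        self.input_dim = input_dim
        self.net = nn.LSTMStack(
            input_dim=input_dim,
            n_layers=config.n_recurrent_layers,
            units=config.units_per_layer,
            output_dim=config.n_classes,
            dropout=config.dropout_rate,
            seed=config.seed,
            return_sequences=False,
        )
        self.history: list[dict] = []

    def _check_windows(self, windows: np.ndarray) -> None:
        if windows.ndim != 3 or windows.shape[1] != self.config.lookback:
            raise ValueError(
                f"{self.config.parameter} model expects windows of length "
                f"{self.config.lookback}, got shape {windows.shape}"
            )

    def fit(self, windows: np.ndarray, labels: np.ndarray) -> "DifficultyModel":
        cfg = self.config
        self._check_windows(windows)
        rng = np.random.default_rng(cfg.seed)
        N = windows.shape[0]
        n_val = int(round(cfg.validation_fraction * N))
        perm = rng.permutation(N)
        va_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("no training windows")
        opt = nn.Adam(lr=cfg.learning_rate, clipnorm=cfg.clipnorm)
        best = np.inf
        best_weights = self.net.get_weights()
        since_best = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(tr_idx)
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self.net.forward(windows[idx], training=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
                self.net.backward(dlogits)
                opt.step(self.net.params, self.net.grads)
                losses.append(loss)
            if va_idx.size:
                logits = self.net.forward(windows[va_idx], training=False)
                monitored, _ = nn.softmax_cross_entropy(logits, labels[va_idx])
            else:
                monitored = float(np.mean(losses))
            self.history.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "monitored_loss": monitored}
            )
            if monitored < best - 1e-6:
                best = monitored
                best_weights = self.net.get_weights()
                since_best = 0
            else:
                since_best += 1
            if since_best >= cfg.patience:
                break
        self.net.set_weights(best_weights)
        return self

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        self._check_windows(windows)
        return nn.softmax(self.net.forward(windows, training=False))

    def predict_classes(self, windows: np.ndarray) -> np.ndarray:
        # argmax with ties broken toward the lower (easier) class.
        return np.argmax(self.predict_proba(windows), axis=1)

    def recommend(self, window: np.ndarray) -> tuple[np.ndarray, str]:
        """Class probabilities and the recommended level for one window."""
        proba = self.predict_proba(window[None])[0]
        return proba, index_to_level(self.config.parameter, int(np.argmax(proba)))


def _save_net(path, net: nn.LSTMStack, config_dict: dict) -> None:
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path.with_suffix(".npz"), *net.get_weights())
    path.with_suffix(".json").write_text(json.dumps(config_dict, indent=2))


def _load_weights(path) -> list[np.ndarray]:
    from pathlib import Path

    with np.load(Path(path).with_suffix(".npz")) as data:
        return [data[k] for k in data.files]


def save_outcome_model(model: OutcomeModel, path) -> None:
    _save_net(path, model.net, {**model.config.__dict__, "input_dim": model.input_dim})


def load_outcome_model(path) -> OutcomeModel:
    import json
    from pathlib import Path

    cfg = json.loads(Path(path).with_suffix(".json").read_text())
    input_dim = cfg.pop("input_dim")
    model = OutcomeModel(OutcomeModelConfig(**cfg), input_dim=input_dim)
    model.net.set_weights(_load_weights(path))
    return model


def save_difficulty_model(model: DifficultyModel, path) -> None:
    _save_net(path, model.net, {**model.config.__dict__, "input_dim": model.input_dim})


def load_difficulty_model(path) -> DifficultyModel:
    import json
    from pathlib import Path

    cfg = json.loads(Path(path).with_suffix(".json").read_text())
    input_dim = cfg.pop("input_dim")
    model = DifficultyModel(DifficultyModelConfig(**cfg), input_dim=input_dim)
    model.net.set_weights(_load_weights(path))
    return model


def build_outcome_model(config: OutcomeModelConfig, input_dim: int = 36) -> OutcomeModel:
    return OutcomeModel(config, input_dim)


def build_difficulty_model(
    parameter: str, config: DifficultyModelConfig | None = None, input_dim: int = 36
) -> DifficultyModel:
    if config is None:
        config = DIFFICULTY_PRESETS[parameter]
    if config.parameter != parameter:
        raise ValueError("config.parameter does not match requested parameter")
    return DifficultyModel(config, input_dim)


# ---------------------------------------------------------------------------
# Random-forest baselines


def _valid_rows(tensor: CohortTensor) -> tuple[np.ndarray, np.ndarray]:
    """Flatten valid time-steps into (rows, per-row labels)."""
    rows, labels = [], []
    for p in range(tensor.n_patients):
        m = int(tensor.lengths[p])
        rows.append(tensor.values[p, :m])
        labels.append(np.repeat(tensor.labels[p][None], m, axis=0))
    return np.concatenate(rows), np.concatenate(labels)


class RFOutcomeBaseline:
    """Per-time-step random-forest regressor of the discharge triple."""

    def __init__(self, config: RFConfig):
        self.config = config
        self.model = RandomForestRegressor(
            n_estimators=config.outcome_n_estimators,
            max_depth=config.outcome_max_depth,
            min_samples_split=config.outcome_min_samples_split,
            min_samples_leaf=config.outcome_min_samples_leaf,
            random_state=config.seed,
            n_jobs=1,
        )

    def fit(self, train: CohortTensor) -> "RFOutcomeBaseline":
        X, y = _valid_rows(train)
        self.model.fit(X, y)
        return self

    def predict_normalized(self, tensor: CohortTensor) -> np.ndarray:
        P, T, F = tensor.values.shape
        flat = self.model.predict(tensor.values.reshape(P * T, F))
        return np.clip(flat.reshape(P, T, 3), 0.0, 1.0)


class RFDifficultyBaseline:
    """Random-forest classifier on flattened lookback windows."""

    def __init__(self, parameter: str, config: RFConfig):
        self.parameter = parameter
        self.config = config
        self.model = RandomForestClassifier(
            n_estimators=config.reco_n_estimators,
            max_depth=config.reco_max_depth,
            min_samples_split=config.reco_min_samples_split,
            min_samples_leaf=config.reco_min_samples_leaf,
            random_state=config.seed,
            n_jobs=1,
        )

    def fit(self, windows: np.ndarray, labels: np.ndarray) -> "RFDifficultyBaseline":
        N = windows.shape[0]
        self.model.fit(windows.reshape(N, -1), labels)
        return self

    def predict_classes(self, windows: np.ndarray) -> np.ndarray:
        N = windows.shape[0]
        return self.model.predict(windows.reshape(N, -1)).astype(int)


def train_rf_baselines(
    train: CohortTensor,
    lookback_train: dict[str, LookbackDataset],
    config: RFConfig,
) -> tuple[RFOutcomeBaseline, dict[str, RFDifficultyBaseline]]:
    """Fit the outcome regressor and the three parameter classifiers with
    the stated hyperparameters on one fold's training data."""
    outcome = RFOutcomeBaseline(config).fit(train)
    classifiers = {}
    for p in ROBOT_PARAMETERS:
        ds = lookback_train[p]
        clf = RFDifficultyBaseline(p, config)
        clf.fit(ds.windows, ds.label_for(p))
        classifiers[p] = clf
    return outcome, classifiers
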