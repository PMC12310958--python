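"""Model-facing arrays: the cohort tensor and lookback window datasets.

The cohort tensor stacks each patient's harmonized, normalized series into a
``patients x time-steps x features`` array (64 x 36 by default) with a
validity mask (padding is a masked all-zero suffix) and the normalized
discharge-score triple as labels. Next to the normalized feature rows it
carries the per-step robot-parameter class indices, from which the
recommendation task's lookback windows and next-session labels are derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .schema import CLINICAL_SCALES, FeatureSchema, ROBOT_PARAMETERS


def build_feature_vector(
    demographics: np.ndarray,
    kinematics: np.ndarray,
    robot_params: np.ndarray,
    game_onehot: np.ndarray,
    time_features: np.ndarray,
    schema: FeatureSchema,
) -> np.ndarray:
    """Concatenate the five normalized groups in schema order."""
    vec = np.concatenate(
        [demographics, kinematics, robot_params, game_onehot, time_features]
    )
    if vec.shape[0] != schema.width:
        raise ValueError(
            f"feature vector has width {vec.shape[0]}, schema expects {schema.width}"
        )
    return vec


@dataclass
class CohortTensor:
    """Harmonized cohort: values, mask, labels, per-step parameter classes."""

    values: np.ndarray  # (P, T, F) float, zeros on padded rows
    mask: np.ndarray  # (P, T) bool, True = real session
    labels: np.ndarray  # (P, 3) normalized discharge scores
    param_classes: np.ndarray  # (P, T, 3) int class ids, -1 on padding
    patient_ids: list[str]
    schema: FeatureSchema

    def __post_init__(self):
        P, T, F = self.values.shape
        if F != self.schema.width:
            raise ValueError(f"tensor width {F} does not match schema {self.schema.width}")
        if self.mask.shape != (P, T) or self.labels.shape != (P, len(CLINICAL_SCALES)):
            raise ValueError("inconsistent tensor component shapes")
        if np.any(np.abs(self.values[~self.mask]) > 0):
            raise ValueError("padded rows must be all-zero")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        return self.mask.sum(axis=1).astype(int)

    def subset(self, indices) -> "CohortTensor":
        indices = np.asarray(indices)
        return CohortTensor(
            values=self.values[indices],
            mask=self.mask[indices],
            labels=self.labels[indices],
            param_classes=self.param_classes[indices],
            patient_ids=[self.patient_ids[i] for i in indices],
            schema=self.schema,
        )

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "cohort_tensor.npz",
            values=self.values,
            mask=self.mask,
            labels=self.labels,
            param_classes=self.param_classes,
        )
        (directory / "patient_ids.json").write_text(json.dumps(self.patient_ids))
        self.schema.save(directory / "feature_schema.json")

    @classmethod
    def load(cls, directory) -> "CohortTensor":
        directory = Path(directory)
        arrays = np.load(directory / "cohort_tensor.npz")
        return cls(
            values=arrays["values"],
            mask=arrays["mask"].astype(bool),
            labels=arrays["labels"],
            param_classes=arrays["param_classes"],
            patient_ids=json.loads((directory / "patient_ids.json").read_text()),
            schema=FeatureSchema.load(directory / "feature_schema.json"),
        )


def assemble_cohort_tensor(
    patient_series: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]],
    schema: FeatureSchema,
    target: int = 64,
) -> CohortTensor:
    """Stack per-patient (id, steps (m, F), label (3,), classes (m, 3))
    into one padded cohort tensor, preserving patient order."""
    P = len(patient_series)
    values = np.zeros((P, target, schema.width))
    mask = np.zeros((P, target), dtype=bool)
    labels = np.zeros((P, len(CLINICAL_SCALES)))
    classes = np.full((P, target, len(ROBOT_PARAMETERS)), -1, dtype=int)
    ids = []
    for i, (pid, steps, label, cls) in enumerate(patient_series):
        m = steps.shape[0]
        if m > target:
            raise ValueError(f"patient {pid} series of length {m} exceeds target {target}")
        if steps.shape[1] != schema.width:
            raise ValueError(
                f"patient {pid} feature width {steps.shape[1]} != schema {schema.width}"
            )
        values[i, :m] = steps
        mask[i, :m] = True
        labels[i] = label
        classes[i, :m] = cls
        ids.append(pid)
    return CohortTensor(
        values=values, mask=mask, labels=labels, param_classes=classes,
        patient_ids=ids, schema=schema,
    )


@dataclass
class LookbackDataset:
    """Sliding windows for next-session parameter recommendation."""

    windows: np.ndarray  # (N, L, F)
    labels: np.ndarray  # (N, 3) int class ids of the *next* session
    provenance: np.ndarray  # (N, 2): (patient index, window end position)
    lookback: int

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def label_for(self, parameter: str) -> np.ndarray:
        return self.labels[:, ROBOT_PARAMETERS.index(parameter)]


def build_lookback_windows(tensor: CohortTensor, lookback: int) -> LookbackDataset:
    """Windows of ``lookback`` consecutive valid steps labelled with the
    immediately following session's parameter classes.

    A patient with m valid steps yields max(0, m - lookback) windows; early
    sessions with fewer than ``lookback`` predecessors are skipped, and no
    window or label ever touches a padded row.
    """
    if lookback < 1:
        raise ValueError("lookback must be >= 1")
    windows, labels, prov = [], [], []
    lengths = tensor.lengths
    for p in range(tensor.n_patients):
        m = int(lengths[p])
        for end in range(lookback - 1, m - 1):
            windows.append(tensor.values[p, end - lookback + 1 : end + 1])
            labels.append(tensor.param_classes[p, end + 1])
            prov.append((p, end))
    if not windows:
        import warnings

        warnings.warn("no lookback windows could be built (series too short)")
        F = tensor.values.shape[2]
        return LookbackDataset(
            windows=np.zeros((0, lookback, F)),
            labels=np.zeros((0, 3), dtype=int),
            provenance=np.zeros((0, 2), dtype=int),
            lookback=lookback,
        )
    return LookbackDataset(
        windows=np.stack(windows),
        labels=np.stack(labels).astype(int),
        provenance=np.array(prov, dtype=int),
        lookback=lookback,
    )
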