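import numpy as np
import pandas as pd
import pytest

from rehabdst import pipeline
from rehabdst.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient cohort exercising both padding and shrinking."""
    config = SimConfig(n_patients=12, seed=11)
    rounds, patients, latents = generate_cohort(config)
    return config, rounds, patients, latents


@pytest.fixture(scope="session")
def prepared(small_cohort):
    _, rounds, patients, _ = small_cohort
    return pipeline.prepare_cohort(rounds, patients)


@pytest.fixture(scope="session")
def fold_tensors(prepared):
    """(train, test, state) for a fixed split of the small cohort."""
    ids = prepared.patient_ids
    train_ids, test_ids = ids[:9], ids[9:]
    state = pipeline.fit_fold_normalizer(prepared, train_ids)
    train = pipeline.build_cohort_tensor(prepared, train_ids, state)
    test = pipeline.build_cohort_tensor(prepared, test_ids, state)
    return train, test, state


def make_sessions(day_games: list[tuple[int, int]], patient_id: str = "P") -> pd.DataFrame:
    """Minimal session frame from (day, game) pairs, in the given order."""
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "date": [f"2024-01-{d + 1:02d}" for d, _ in day_games],
            "day": [d for d, _ in day_games],
            "game_id": [g for _, g in day_games],
            "n_rounds": 1,
            "stiffness": "Mid",
            "weight": "Mid",
            "viscosity": "Low",
        }
    )
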