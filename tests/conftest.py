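"""Shared fixtures: small synthetic cohorts and prediction tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dpfair.evaluation import PredictionTable
from dpfair.synthetic import (
    DatasetSpec,
    SubgroupSpec,
    generate_cxr_like,
    generate_ct_like,
)


def two_group_spec(
    n_patients: int = 200,
    image_shape=(16, 16),
    labels=("finding_a", "finding_left"),
    prevalence=0.4,
    difficulty_ratio: float = 1.0,
    images_per_patient=1,
    seed: int = 0,
    proportions=(0.65, 0.35),
) -> DatasetSpec:
    """Minimal two-subgroup 2D spec used across tests."""
    prev = {l: prevalence for l in labels}
    return DatasetSpec(
        n_patients=n_patients,
        image_shape=tuple(image_shape),
        labels=tuple(labels),
        subgroups=(
            SubgroupSpec("g_major", proportions[0], prev, 1.0, 0.5, sex="male"),
            SubgroupSpec(
                "g_minor", proportions[1], prev, difficulty_ratio, 0.5, sex="female"
            ),
        ),
        images_per_patient=images_per_patient,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cxr_set():
    return generate_cxr_like(two_group_spec())


@pytest.fixture(scope="session")
def small_ct_set():
    spec = DatasetSpec(
        n_patients=60,
        image_shape=(12, 12, 12),
        labels=("tumor",),
        subgroups=(
            SubgroupSpec("all", 1.0, {"tumor": 0.5}, 1.0, sex="male"),
        ),
        seed=3,
    )
    return generate_ct_like(spec)


def make_prediction_table(
    n: int = 200,
    labels=("a", "b"),
    separation: float = 1.5,
    seed: int = 0,
    sex_fraction: float = 0.5,
) -> PredictionTable:
    """Scores drawn from class-conditional normals pushed through a sigmoid."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n)],
            "patient_id": [f"p{i}" for i in range(n)],
            "sex": np.where(rng.random(n) < sex_fraction, "female", "male"),
            "age_group": rng.choice(["[0,30)", "[30,60)", "[60,70)"], size=n),
        }
    )
    for label in labels:
        truth = (rng.random(n) < 0.4).astype(int)
        raw = rng.normal(size=n) + separation * truth
        frame[f"y_true_{label}"] = truth
        frame[f"y_score_{label}"] = 1.0 / (1.0 + np.exp(-raw))
    return PredictionTable(frame, tuple(labels))


@pytest.fixture()
def prediction_table():
    return make_prediction_table()
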