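"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hrvoutcome import (
    CohortConfig,
    CohortDataset,
    DistanceFeatureConfig,
    FEATURE_NAMES,
    Patient,
    gen_cohort,
    sliding_dist,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_feature_table(patient_id: str, n_rows: int, rng: np.random.Generator,
                       scale: float = 1.0) -> pd.DataFrame:
    """A hand-made epoch-feature table with positive iid noise values."""
    data = {name: np.abs(rng.normal(10.0 * scale, 2.0, size=n_rows)) + 0.1
            for name in FEATURE_NAMES}
    table = pd.DataFrame(data)
    table.insert(0, "time_point", np.arange(1, n_rows + 1))
    table.insert(0, "patient_id", patient_id)
    return table


def make_noise_cohort(seed: int, n_survivors: int = 10, n_non_survivors: int = 5,
                      n_rows: int = 12, n_window: int = 8) -> CohortDataset:
    """A feature-level cohort with no outcome signal anywhere."""
    rng = np.random.default_rng(seed)
    dconf = DistanceFeatureConfig(n_window=n_window)
    patients = []
    for prefix, label, count in (("S", 0, n_survivors), ("N", 1, n_non_survivors)):
        for i in range(count):
            pid = f"{prefix}{i + 1:02d}"
            feat = make_feature_table(pid, n_rows, rng)
            scores = {"APACHE_II": float(rng.normal(15, 5)),
                      "APACHE_III": float(rng.normal(55, 15)),
                      "SAPS": float(rng.normal(40, 10))}
            patients.append(Patient(pid, label, scores, feat, sliding_dist(feat, dconf)))
    return CohortDataset(patients)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-structured default cohort: 21 survivors, 5 non-survivors,
    24-h records, 2 truncated non-survivors."""
    dataset, truth = gen_cohort(CohortConfig(rng_seed=20))
    return dataset, truth


@pytest.fixture(scope="session")
def short_cohort():
    """A faster cohort with the default group structure but 6-h records."""
    dataset, truth = gen_cohort(CohortConfig(record_hours=6.0, rng_seed=21))
    return dataset, truth
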