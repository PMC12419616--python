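"""Shared fixtures: the frozen synthetic study cohort and its fitted models.

The expensive objects (cohort, resampled matrices, per-horizon models,
attribution panels) are built once per session and reused across unit and
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import predeath as pdth

STUDY_SEED = 0
STUDY_N = 500
STUDY_HORIZONS = (1, 5, 15, 30, 45, 60, 75, 90)
DECAY_HORIZONS = (1, 15, 30, 45, 60, 75, 90)


@pytest.fixture(scope="session")
def study_cohort():
    spec, params = pdth.three_subtype_scenario(n_patients=STUDY_N,
                                               seed=STUDY_SEED)
    events, truth = pdth.generate_cohort(spec, params)
    return {"spec": spec, "params": params, "events": events, "truth": truth}


@pytest.fixture(scope="session")
def study_matrices(study_cohort):
    events = pdth.dedup_first_per_day(study_cohort["events"])
    kept, _ = pdth.coverage_filter(events)
    return pdth.resample_cohort(events, window_days=5, t_max=180,
                                parameters=kept)


@pytest.fixture(scope="session")
def study_datasets(study_matrices):
    return {n: pdth.build_horizon_dataset(study_matrices, n)
            for n in STUDY_HORIZONS}


@pytest.fixture(scope="session")
def study_split(study_datasets):
    return pdth.grouped_split(study_datasets[1], seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_family(study_matrices):
    return pdth.train_model_family(study_matrices,
                                   horizons=list(STUDY_HORIZONS),
                                   seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_panels(study_family, study_datasets):
    return pdth.compute_panels(study_family, study_datasets, subset="all")


@pytest.fixture(scope="session")
def study_correct_panels(study_panels):
    return {n: pdth.select_correct_positives(p)
            for n, p in study_panels.items()}


@pytest.fixture(scope="session")
def study_behavior(study_correct_panels):
    return pdth.behavior_matrix(study_correct_panels, already_filtered=True)


@pytest.fixture(scope="session")
def study_truth_labels(study_cohort):
    return study_cohort["truth"].set_index("patient_id")["subtype"]


def tiny_events(rows):
    """Long-format event table from (patient, day, parameter, value) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "days_before_death",
                                       "parameter", "value"])
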