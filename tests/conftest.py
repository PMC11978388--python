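"""Shared fixtures: hand-built mini cohorts and session-scoped synthetic runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import survpath as sp


def make_mini_cohort():
    """Three patients, two variables, hand-checkable observations."""
    dictionary = sp.CovariateDictionary([
        sp.Variable("afp", "continuous", "IU/ml", 0, 1e6),
        sp.Variable("diameter_mm", "continuous", "mm", 0, 400),
    ])
    obs = pd.DataFrame([
        # pid, variable, value, time
        ("A", "afp", 10.0, 0.0), ("A", "diameter_mm", 80.0, 0.0),
        ("A", "afp", 30.0, 2.0), ("A", "diameter_mm", 85.0, 2.0),
        ("A", "afp", 12.0, 3.5), ("A", "afp", 50.0, 5.2),
        ("A", "diameter_mm", 90.0, 5.0),
        ("B", "afp", 5.0, -0.5), ("B", "diameter_mm", 40.0, -0.5),
        ("C", "afp", 400.0, 0.5), ("C", "diameter_mm", 120.0, 0.5),
        ("C", "afp", 500.0, 2.5),
    ], columns=["patient_id", "variable", "value", "time_months"])
    outcomes = pd.DataFrame({
        "patient_id": ["A", "B", "C"],
        "os_months": [30.0, 50.0, 4.0],
        "event": [1, 0, 1],
    })
    cfs = pd.DataFrame(columns=["patient_id", "start_months", "end_months"])
    return sp.Cohort(obs, outcomes, cfs, dictionary)


@pytest.fixture
def mini_cohort():
    return make_mini_cohort()


@pytest.fixture(scope="session")
def synthetic_cohort():
    cohort, truth = sp.generate(sp.GeneratorConfig(n_patients=400, seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def synthetic_table(synthetic_cohort):
    cohort, _ = synthetic_cohort
    return sp.build_slice_table(cohort)


@pytest.fixture(scope="session")
def fitted_tree(synthetic_table):
    return sp.grow(synthetic_table)
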