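"""Shared fixtures: hand-built toy cohorts and synthetic presets."""

from __future__ import annotations

import pytest

from agestage.cohort_io import (CohortTable, IndividualRecord, FAW_SCHEMA,
                                FEMALE, MALE, UNKNOWN)


def make_individual(ind_id, sex, stages, eggs=None):
    """Build a record from a list of per-day stage labels."""
    history = [(age, stage) for age, stage in enumerate(stages)]
    return IndividualRecord(id=ind_id, sex=sex, history=history,
                           daily_eggs=dict(eggs or {}))


def make_cohort(specs):
    """specs: list of (id, sex, [stage per day], {age: eggs})."""
    individuals = [make_individual(i, s, st, e) for i, s, st, e in specs]
    return CohortTable(schema=FAW_SCHEMA, individuals=individuals)


@pytest.fixture
def two_egg_cohort():
    """A dies as egg after day 2; B hatches to L1 on day 3."""
    return make_cohort([
        ("A", UNKNOWN, ["EGG", "EGG", "EGG"], {}),
        ("B", UNKNOWN, ["EGG", "EGG", "EGG", "L1"], {}),
    ])


@pytest.fixture
def toy_pair_cohort():
    """1 female laying 10 eggs on her first adult day, 1 male."""
    return make_cohort([
        ("F", FEMALE, ["EGG", "ADULT_F"], {1: 10}),
        ("M", MALE, ["EGG", "ADULT_M"], {}),
    ])


@pytest.fixture
def three_individual_cohort():
    """Female laying 5 eggs on day 30, a male, and a pre-adult death."""
    f_stages = (["EGG"] * 3 + ["L1"] * 2 + ["L2"] * 2 + ["L3"] * 2
                + ["L4"] * 2 + ["L5"] * 3 + ["L6"] * 4 + ["PUPA"] * 9
                + ["ADULT_F"] * 8)
    m_stages = (["EGG"] * 3 + ["L1"] * 2 + ["L2"] * 2 + ["L3"] * 2
                + ["L4"] * 2 + ["L5"] * 3 + ["L6"] * 5 + ["PUPA"] * 9
                + ["ADULT_M"] * 10)
    d_stages = ["EGG"] * 3 + ["L1"] * 2 + ["L2"] * 1
    return make_cohort([
        ("f1", FEMALE, f_stages, {30: 5}),
        ("m1", MALE, m_stages, {}),
        ("d1", UNKNOWN, d_stages, {}),
    ])


@pytest.fixture
def clone_cohort():
    """Identical life histories: every resampling statistic is invariant."""
    stages = ["EGG"] * 3 + ["L1"] * 2 + ["ADULT_F"] * 4
    eggs = {6: 20, 7: 30}
    return make_cohort([(f"c{i}", FEMALE, list(stages), dict(eggs))
                        for i in range(10)])


@pytest.fixture(scope="session")
def faw_cohort():
    from agestage.synthetic_cohorts import preset, generate_cohort
    return generate_cohort(preset("faw-like"), seed=1)


@pytest.fixture(scope="session")
def corn_cohort():
    from agestage.synthetic_cohorts import preset, generate_cohort
    return generate_cohort(preset("corn-like"), seed=2)
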