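"""Shared fixtures: small synthetic cohorts and a hand-built filter fixture."""

import numpy as np
import pandas as pd
import pytest

from elnthresh import synthetic_cohort as sc


@pytest.fixture(scope="session")
def migration_cohort():
    """US-like stage-migration cohort, small enough for unit tests."""
    return sc.generate_cohort(sc.scenario_config("migration", 4000, 11))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with full-knowledge detection and no direct ELN effect."""
    return sc.generate_cohort(sc.scenario_config("null", 4000, 12))


def _valid_record(i, **overrides):
    base = dict(
        id=f"R{i:02d}",
        sex="male",
        age_years=62.0,
        diagnosis_year=2012,
        location="antrum_pylorus",
        local_invasion="muscularis_subserosa",
        grade="poor",
        size_cm=3.5,
        resection_type="partial_subtotal",
        margin_positive=0,
        eln=15,
        pln=2,
        survival_months=36.0,
        death=0,
    )
    base.update(overrides)
    return base


@pytest.fixture()
def filter_fixture():
    """Ten records, exactly four eligibility violations (one per rule)."""
    rows = [
        _valid_record(0),
        _valid_record(1, pln=0, death=1, survival_months=20.0),
        _valid_record(2, eln=40, pln=17),
        _valid_record(3, sex="female", grade="well"),
        _valid_record(4, age_years=81.0),
        _valid_record(5, eln=8, pln=8),
        _valid_record(6, diagnosis_year=2009),          # outside 2010-2016
        _valid_record(7, eln=0, pln=0),                 # no examined nodes
        _valid_record(8, survival_months=2.0, death=1), # perioperative death
        _valid_record(9, grade=pd.NA),                  # missing analysis field
    ]
    return pd.DataFrame(rows)
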