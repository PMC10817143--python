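"""Shared fixtures: synthetic references, cohorts, and a hand-built
eligibility fixture exercising every exclusion rule."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gwgcharts.harmonize import derive_subject_fields, derive_visit_fields
from gwgcharts.synthetic import (CohortConfig, default_bmi_reference,
                                 default_height_reference, generate_cohort)


@pytest.fixture(scope="session")
def height_ref():
    return default_height_reference()


@pytest.fixture(scope="session")
def bmi_ref():
    return default_bmi_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """3 sites x 60 subjects, default study conditions, fixed seed."""
    cfg = CohortConfig(n_sites=3, subjects_per_site=60, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def derived_cohort(small_cohort, height_ref, bmi_ref):
    subjects, visits, truth = small_cohort
    sd = derive_subject_fields(subjects, height_ref, bmi_ref)
    vd = derive_visit_fields(visits, sd)
    return sd, vd, truth


# ---------------------------------------------------------------------------
# hand-built eligibility fixture: 60 subjects, every exclusion rule once
# ---------------------------------------------------------------------------

def _subject(i: int, **over) -> dict:
    row = {
        "subject_id": f"F{i:03d}",
        "site": "site_A" if i % 2 else "site_B",
        "date_of_birth": "2003-05-10",     # age 15 at conception 2019-03-15
        "lmp_date": "2019-03-01",
        "prepreg_weight_kg": 55.0,
        "prepreg_weight_source": "measured",
        "height_cm": 158.0,
        "prepreg_bmi": round(55.0 / 1.58 ** 2, 2),
        "flag_hypertension": False,
        "flag_preeclampsia": False,
        "flag_diabetes": False,
        "flag_tuberculosis": False,
        "flag_cardiovascular": False,
        "ga_birth_weeks": 39,
        "birth_weight_g": 3300.0,
        "birth_length_cm": 49.0,
    }
    row.update(over)
    return row


def _visits(subject_id: str, weeks=None, rate: float = 0.3,
            base: float = 55.0, bumps: dict | None = None) -> list[dict]:
    weeks = weeks if weeks is not None else [8, 12, 16, 20, 24, 28, 32, 36]
    out = []
    for w in weeks:
        wt = round(base + rate * w, 1)
        if bumps and w in bumps:
            wt = round(wt + bumps[w], 1)
        out.append({"subject_id": subject_id, "ga_weeks": w, "weight_kg": wt})
    return out


@pytest.fixture(scope="session")
def eligibility_fixture(height_ref, bmi_ref):
    """(subjects, visits, expected ledger rows) for the cleaning stage.

    60 subjects: 44 fully eligible, and two per exclusion criterion in the
    documented ledger order (the trajectory criterion removes two visits
    but no subjects).
    """
    subjects, visits = [], []
    i = 0

    def add(n=1, sub_over=None, visit_kw=None):
        nonlocal i
        for _ in range(n):
            i += 1
            s = _subject(i, **(sub_over or {}))
            subjects.append(s)
            visits.extend(_visits(s["subject_id"], **(visit_kw or {})))

    add(n=42)                                            # eligible
    # two eligible subjects with an implausible +10 kg visit at week 20:
    # the visit is removed, the subject stays -> still 44 eligible subjects
    add(n=2, visit_kw={"bumps": {20: 10.0}})
    # age: one too old (20), one too young (9)
    add(sub_over={"date_of_birth": "1999-01-01"})
    add(sub_over={"date_of_birth": "2010-01-01"})
    # visit coverage: no second-trimester visit / no third-trimester visit
    add(visit_kw={"weeks": [8, 12, 28, 32, 36]})
    add(visit_kw={"weeks": [8, 12, 16, 20, 24]})
    # term birth: preterm and post-term
    add(sub_over={"ga_birth_weeks": 36})
    add(sub_over={"ga_birth_weeks": 43})
    # birth weight outside 2500-4000 g
    add(sub_over={"birth_weight_g": 2450.0})
    add(sub_over={"birth_weight_g": 4100.0})
    # disease flags
    add(sub_over={"flag_diabetes": True})
    add(sub_over={"flag_preeclampsia": True})
    # stunting: very short for age
    add(n=2, sub_over={"height_cm": 140.0,
                       "prepreg_bmi": round(55.0 / 1.40 ** 2, 2)})
    # maximal cumulative GWG >= 30 kg (one exactly 30.0: inclusive exclusion)
    add(visit_kw={"bumps": {36: 30.0 - 0.3 * 36}})       # max GWG exactly 30.0
    add(visit_kw={"rate": 0.9})                          # max GWG 32.4
    # completeness: missing birth length / missing pre-pregnancy weight
    add(sub_over={"birth_length_cm": np.nan})
    add(sub_over={"prepreg_weight_kg": np.nan, "prepreg_bmi": np.nan})

    assert i == 60
    expected = {
        "age": 2, "visit_coverage": 2, "term_birth": 2, "birth_weight": 2,
        "diseases": 2, "stunting": 2, "gwg_ge_30": 2,
        "implausible_trajectory": 0, "completeness": 2,
    }
    subj = derive_subject_fields(pd.DataFrame(subjects), height_ref, bmi_ref)
    vis = derive_visit_fields(pd.DataFrame(visits), subj)
    return subj, vis, expected
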