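"""Shared fixtures: hand-built micro-cohorts and one mid-size synthetic cohort."""

import numpy as np
import pandas as pd
import pytest

import cardioscreen as cs
from cardioscreen.simulate import ClaimsCohort


def make_cohort(persons=None, enroll=None, dx=None, rx=None,
                pregnancies=None, links=None, gem=None) -> ClaimsCohort:
    """Assemble a ClaimsCohort from partial row-dict lists (rest empty)."""
    def df(rows, columns):
        if rows:
            return pd.DataFrame(rows)
        return pd.DataFrame(columns=columns)

    return ClaimsCohort(
        persons=df(persons, ["person_id", "sex", "birth_year", "family_key"]),
        enroll=df(enroll, ["person_id", "start_day", "end_day", "rx_benefit"]),
        dx=df(dx, ["person_id", "day", "code", "vocabulary"]),
        rx=df(rx, ["person_id", "day", "code"]),
        pregnancies=df(pregnancies, ["pregnancy_id", "mother_id", "lmp_day",
                                     "end_day", "delivery_year", "n_fetuses"]),
        links=df(links, ["pregnancy_id", "infant_id", "death_day"]),
        gem=df(gem, ["source", "target", "flags"]),
    )


def base_family(preg_id=0, mother=0, father=1, infant=2, end_day=273,
                year=2015, n_fetuses=1, mother_age=31):
    """One fully eligible pregnancy family; tests mutate pieces."""
    persons = [
        {"person_id": mother, "sex": "F", "birth_year": year - mother_age,
         "family_key": preg_id},
        {"person_id": father, "sex": "M", "birth_year": year - 33,
         "family_key": preg_id},
        {"person_id": infant, "sex": "F", "birth_year": year,
         "family_key": preg_id},
    ]
    enroll = [
        {"person_id": mother, "start_day": -400, "end_day": end_day + 400,
         "rx_benefit": True},
        {"person_id": father, "start_day": -400, "end_day": 100,
         "rx_benefit": True},
        {"person_id": infant, "start_day": end_day, "end_day": end_day + 400,
         "rx_benefit": True},
    ]
    pregnancies = [{"pregnancy_id": preg_id, "mother_id": mother,
                    "lmp_day": 0, "end_day": end_day,
                    "delivery_year": year, "n_fetuses": n_fetuses}]
    links = [{"pregnancy_id": preg_id, "infant_id": infant,
              "death_day": np.nan}]
    return persons, enroll, pregnancies, links


@pytest.fixture(scope="session")
def mid_cohort():
    """One 20k-pregnancy cohort with the default planted scenario."""
    cfg = cs.default_config(n_pregnancies=20_000, seed=7)
    cohort, truth = cs.generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def mid_prepared(mid_cohort):
    """Eligibility, father links, outcomes and ages for the mid cohort."""
    from cardioscreen import cohort as cb
    from cardioscreen.pipeline import maternal_ages

    cfg, cohort, truth = mid_cohort
    eligible, tally = cs.apply_eligibility(cohort)
    ids = sorted(eligible)
    gem = cb.gem_from_frame(cohort.gem)
    father_map = cs.link_fathers(cohort, eligible)
    outcomes = cs.flag_outcomes(cohort, ids, cs.default_code_lists())
    ages = maternal_ages(cohort, ids)
    return dict(cfg=cfg, cohort=cohort, truth=truth, eligible=eligible,
                tally=tally, ids=ids, gem=gem, father_map=father_map,
                outcomes=outcomes, ages=ages)
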