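from datetime import date

import numpy as np
import pytest

from trajmorbid.sequences import DEFAULT_CATEGORIES, build_alphabet
from trajmorbid.synthetic import ClassSpec, PersonRecord, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def alphabet():
    return build_alphabet()


@pytest.fixture(scope="session")
def alphabet2():
    return build_alphabet(("A", "B"))


def make_person(pid="p1", birth=date(1985, 3, 1), censor=date(2016, 12, 31),
                reason="end_of_followup", scz=None, events=None, sex="M"):
    return PersonRecord(person_id=pid, sex=sex, birth_date=birth,
                        censor_date=censor, censor_reason=reason,
                        scz_first_date=scz, events=events or {})


def hazard_vector(categories=DEFAULT_CATEGORIES, base=0.001, **kw):
    h = np.full(len(categories), base)
    idx = {c: i for i, c in enumerate(categories)}
    for k, v in kw.items():
        h[idx[k]] = v
    return h


def three_class_config(n_cases, seed, sep=0.15):
    """Three well-separated latent classes: childhood-only, substance-only,
    and essentially no comorbidity."""
    classes = [
        ClassSpec("childhood", 1 / 3, hazard_vector(F9=sep),
                  scz_onset_mean=20.0),
        ClassSpec("substance", 1 / 3, hazard_vector(F1=sep)),
        ClassSpec("none", 1 / 3, hazard_vector()),
    ]
    return SimConfig(n_cases=n_cases, n_controls_per_case=0,
                     latent_classes=classes, covariates=[], seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    """200 cases + controls from the default 5-class world."""
    return simulate_cohort(SimConfig(n_cases=200, seed=42))


@pytest.fixture(scope="session")
def small_cases(small_cohort):
    return [p for p in small_cohort if p.scz_first_date is not None]
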