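"""Synthetic registry cohorts with planted latent trajectory structure.

Emulates a national-registry birth cohort (born 1981-2002, followed to
end 2016) in which every case carries an index schizophrenia diagnosis
and accrues first diagnoses in eight comorbid psychiatric categories,
with censoring by death, emigration or end of follow-up.  Latent
trajectory classes plant the structure the downstream pipeline is meant
to recover: class-specific per-category hazards, pairwise hazard
multipliers that switch on at the prior diagnosis date, class-shifted
covariates and overdispersed hospitalization outcomes.

Event times are drawn in continuous time from piecewise-constant
exponential rates ``lambda = -ln(1 - h)`` equivalent to the stated
per-year probabilities ``h``, so a constant yearly hazard ``h`` yields
the geometric cumulative incidence ``1 - (1 - h)**t`` exactly and a
pairwise multiplier ``m`` is the true Cox hazard ratio.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

from .sequences import DAYS_PER_YEAR, DEFAULT_CATEGORIES

__all__ = [
    "CovariateSpec",
    "ClassSpec",
    "SimConfig",
    "PersonRecord",
    "default_classes",
    "default_covariates",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Baseline distribution of one covariate: ``continuous`` is normal
    (mean, sd); ``binary`` is Bernoulli with baseline probability ``mean``."""

    name: str
    kind: str = "continuous"  # or "binary"
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "binary" and not 0 <= self.mean <= 1:
            raise ValueError("binary covariate baseline must be a probability")


@dataclass
class ClassSpec:
    """One latent trajectory class.

    ``base_hazard`` are per-year first-diagnosis probabilities per
    category; ``pair_multipliers[i, j]`` multiplies the rate of category
    ``j`` once category ``i`` has been diagnosed.  ``covariate_shifts``
    are mean shifts (continuous) or log-odds shifts (binary) relative to
    the covariate baseline.  ``hospitalization_mean`` is the expected
    yearly number of admissions after the index diagnosis.
    """

    name: str
    weight: float
    base_hazard: np.ndarray
    pair_multipliers: np.ndarray | None = None
    scz_onset_mean: float = 22.0
    scz_onset_sd: float = 4.0
    covariate_shifts: dict = field(default_factory=dict)
    hospitalization_mean: float = 0.5

    def __post_init__(self) -> None:
        self.base_hazard = np.asarray(self.base_hazard, dtype=float)
        if np.any(self.base_hazard < 0) or np.any(self.base_hazard > 1):
            raise ValueError(f"class {self.name}: hazards must lie in [0, 1]")
        if not 0 <= self.weight <= 1:
            raise ValueError(f"class {self.name}: weight must lie in [0, 1]")
        c = len(self.base_hazard)
        if self.pair_multipliers is None:
            self.pair_multipliers = np.ones((c, c))
        self.pair_multipliers = np.asarray(self.pair_multipliers, dtype=float)
        if self.pair_multipliers.shape != (c, c):
            raise ValueError("pair_multipliers must be (C, C)")
        if np.any(self.pair_multipliers < 0):
            raise ValueError("pair multipliers must be nonnegative")


def default_classes(categories=DEFAULT_CATEGORIES) -> list[ClassSpec]:
    """Five latent classes emulating the canonical trajectory subgroups:
    childhood-onset comorbidity, multiple adult comorbidities, mood-only,
    substance abuse, and little comorbidity; weights follow the relative
    subgroup sizes reported for this kind of cohort (~0.11/0.29/0.14/0.13/0.33).
    """
    c = len(categories)
    idx = {lab: i for i, lab in enumerate(categories)}

    def hz(base=0.003, **kw):
        h = np.full(c, base)
        for lab, v in kw.items():
            h[idx[lab]] = v
        return h

    def mult(pairs):
        m = np.ones((c, c))
        for (a, b), v in pairs.items():
            m[idx[a], idx[b]] = v
        return m

    return [
        ClassSpec("childhood", 0.11,
                  hz(F9=0.10, F84=0.02, F70=0.015),
                  scz_onset_mean=19.0, scz_onset_sd=3.0,
                  covariate_shifts={"maternal_scz": 0.8},
                  hospitalization_mean=0.4),
        ClassSpec("adult_multi", 0.29,
                  hz(0.005, F3=0.05, F4=0.035, F60=0.04, F1=0.02),
                  mult({("F3", "F60"): 2.0, ("F1", "F60"): 2.0,
                        ("F60", "F1"): 2.0}),
                  scz_onset_mean=23.0,
                  covariate_shifts={"maternal_psych": 0.6,
                                    "bacterial_infection": 0.5},
                  hospitalization_mean=0.8),
        ClassSpec("mood_only", 0.14, hz(0.002, F3=0.07),
                  scz_onset_mean=24.0, hospitalization_mean=0.4),
        ClassSpec("substance", 0.13, hz(0.003, F1=0.11, F60=0.012),
                  scz_onset_mean=22.0,
                  covariate_shifts={"pgs_edu": -0.3, "maternal_psych": 0.4},
                  hospitalization_mean=1.0),
        ClassSpec("low", 0.33, hz(0.0015), scz_onset_mean=23.0,
                  hospitalization_mean=0.3),
    ]


def default_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("pgs_edu", "continuous", 0.0, 1.0),
        CovariateSpec("maternal_age", "continuous", 27.0, 5.0),
        CovariateSpec("bacterial_infection", "binary", 0.30),
        CovariateSpec("maternal_psych", "binary", 0.20),
        CovariateSpec("maternal_scz", "binary", 0.02),
    ]


@dataclass
class SimConfig:
    """Simulation configuration; defaults mirror a 1981-2002 birth cohort
    followed to the end of 2016 with two matched controls per case."""

    n_cases: int = 500
    n_controls_per_case: int = 2
    birth_window: tuple[int, int] = (1981, 2002)
    followup_end: date = date(2016, 12, 31)
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    latent_classes: list[ClassSpec] | None = None
    covariates: list[CovariateSpec] | None = None
    death_hazard: float = 0.001
    emigration_hazard: float = 0.0005
    control_hazard_scale: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_classes is None:
            self.latent_classes = default_classes(self.categories)
        if self.covariates is None:
            self.covariates = default_covariates()
        for h in (self.death_hazard, self.emigration_hazard):
            if not 0 <= h <= 1:
                raise ValueError("death/emigration hazards must lie in [0, 1]")
        if self.birth_window[0] > self.birth_window[1]:
            raise ValueError("empty birth window")
        w = sum(c.weight for c in self.latent_classes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"class weights sum to {w}, not 1")
        for c in self.latent_classes:
            if len(c.base_hazard) != len(self.categories):
                raise ValueError(f"class {c.name}: hazard vector length "
                                 "does not match categories")


@dataclass
class PersonRecord:
    """One individual's registry record."""

    person_id: str
    sex: str  # "M" | "F"
    birth_date: date
    censor_date: date
    censor_reason: str  # death | emigration | end_of_followup
    scz_first_date: date | None = None
    events: dict = field(default_factory=dict)  # category -> first date
    covariates: dict = field(default_factory=dict)
    outcomes: dict = field(default_factory=dict)
    latent_class: str | None = None

    def validate(self) -> None:
        for cat, d in self.events.items():
            if not (self.birth_date <= d <= self.censor_date):
                raise ValueError(
                    f"person {self.person_id}: {cat} event on {d} outside "
                    f"[{self.birth_date}, {self.censor_date}]")


def _rate(p: float) -> float:
    """Instantaneous rate equivalent to a per-year probability."""
    return -math.log1p(-p) if p < 1 else math.inf


def _date_at(birth: date, years: float) -> date:
    return birth + timedelta(days=int(round(years * DAYS_PER_YEAR)))


def _simulate_events(rng, base_hazard, multipliers, censor_years):
    """Continuous-time competing-risks draw of first-diagnosis ages."""
    c = len(base_hazard)
    base_rate = np.array([_rate(h) for h in base_hazard])
    diagnosed: dict[int, float] = {}
    t = 0.0
    while len(diagnosed) < c:
        rates = np.array([
            0.0 if j in diagnosed else
            base_rate[j] * np.prod([multipliers[i, j] for i in diagnosed])
            for j in range(c)
        ])
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= censor_years:
            break
        j = rng.choice(c, p=rates / total)
        diagnosed[j] = t
    return diagnosed


def _draw_covariates(rng, specs, shifts):
    out = {}
    for s in specs:
        shift = shifts.get(s.name, 0.0)
        if s.kind == "continuous":
            out[s.name] = float(rng.normal(s.mean + shift, s.sd))
        else:
            logit = math.log(s.mean / (1 - s.mean)) if 0 < s.mean < 1 else (
                math.inf if s.mean == 1 else -math.inf)
            p = 1 / (1 + math.exp(-(logit + shift)))
            out[s.name] = float(rng.random() < p)
    return out


def simulate_cohort(config: SimConfig) -> list[PersonRecord]:
    """Simulate cases plus age- and sex-matched controls (controls reuse
    case birth dates and sexes, with scaled population-level hazards and
    no index diagnosis)."""
    rng = np.random.default_rng(config.seed)
    cats = config.categories
    classes = config.latent_classes
    weights = np.array([c.weight for c in classes])
    y0, y1 = config.birth_window
    start = date(y0, 1, 1)
    span_days = (date(y1, 12, 31) - start).days
    pop_hazard = np.average([c.base_hazard for c in classes], axis=0,
                            weights=weights)
    ctrl_hazard = np.clip(pop_hazard * config.control_hazard_scale, 0, 1)
    eye = np.ones((len(cats), len(cats)))
    persons: list[PersonRecord] = []

    for i in range(config.n_cases):
        k = int(rng.choice(len(classes), p=weights))
        spec = classes[k]
        birth = start + timedelta(days=int(rng.integers(0, span_days + 1)))
        sex = "M" if rng.random() < 0.55 else "F"
        fu_years = (config.followup_end - birth).days / DAYS_PER_YEAR

        def censoring(fu_years):
            t_death = (rng.exponential(1 / _rate(config.death_hazard))
                       if config.death_hazard > 0 else math.inf)
            t_emig = (rng.exponential(1 / _rate(config.emigration_hazard))
                      if config.emigration_hazard > 0 else math.inf)
            t = min(t_death, t_emig, fu_years)
            reason = ("death" if t == t_death else
                      "emigration" if t == t_emig else "end_of_followup")
            return t, reason

        # index diagnosis age: cohort membership requires the diagnosis to
        # occur during follow-up, so censoring is drawn conditionally after it
        hi = min(34.0, fu_years)
        if hi <= 10.0:
            onset = rng.uniform(0.5 * fu_years, fu_years)
        else:
            onset = float(np.clip(rng.normal(spec.scz_onset_mean,
                                             spec.scz_onset_sd), 10.0, hi))
        for _ in range(100):
            cens_years, reason = censoring(fu_years)
            if cens_years >= onset:
                break
        else:
            cens_years, reason = fu_years, "end_of_followup"
        events_t = _simulate_events(rng, spec.base_hazard,
                                    spec.pair_multipliers, cens_years)
        censor_date = (config.followup_end if reason == "end_of_followup"
                       else _date_at(birth, cens_years))
        ev = {cats[j]: min(_date_at(birth, t), censor_date)
              for j, t in events_t.items()}
        post_years = max(cens_years - onset, 0.0)
        mu = spec.hospitalization_mean * post_years
        disp = 2.0
        n_hosp = (int(rng.negative_binomial(disp, disp / (disp + mu)))
                  if mu > 0 else 0)
        days_hosp = float(round(rng.gamma(n_hosp, 14.0), 1)) if n_hosp else 0.0
        case = PersonRecord(
            person_id=f"case{i:06d}", sex=sex, birth_date=birth,
            censor_date=censor_date, censor_reason=reason,
            scz_first_date=min(_date_at(birth, onset), censor_date),
            events=ev,
            covariates=_draw_covariates(rng, config.covariates,
                                        spec.covariate_shifts),
            outcomes={"n_hospitalizations": n_hosp,
                      "days_hospitalized": days_hosp},
            latent_class=spec.name)
        case.validate()
        persons.append(case)

        for r in range(config.n_controls_per_case):
            c_cens, c_reason = censoring(fu_years)
            c_censor_date = (config.followup_end if c_reason == "end_of_followup"
                             else _date_at(birth, c_cens))
            c_events = _simulate_events(rng, ctrl_hazard, eye, c_cens)
            ctrl = PersonRecord(
                person_id=f"ctrl{i:06d}_{r}", sex=sex, birth_date=birth,
                censor_date=c_censor_date, censor_reason=c_reason,
                events={cats[j]: min(_date_at(birth, t), c_censor_date)
                        for j, t in c_events.items()},
                covariates=_draw_covariates(rng, config.covariates, {}),
                outcomes={"n_hospitalizations": 0, "days_hospitalized": 0.0},
                latent_class=None)
            ctrl.validate()
            persons.append(ctrl)
    return persons


# ---------------------------------------------------------------------------
# Cohort I/O: persons / events / covariates / outcomes CSVs plus a separate
# latent-class truth file (simulation ground truth is not a registry field).

_PERSON_HEADER = ["person_id", "sex", "birth_date", "censor_date",
                  "censor_reason", "scz_first_date"]


def write_cohort(persons, directory) -> None:
    import os

    os.makedirs(directory, exist_ok=True)
    j = lambda name: os.path.join(directory, name)
    with open(j("persons.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_PERSON_HEADER)
        for p in persons:
            w.writerow([p.person_id, p.sex, p.birth_date.isoformat(),
                        p.censor_date.isoformat(), p.censor_reason,
                        p.scz_first_date.isoformat() if p.scz_first_date else ""])
    with open(j("events.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "category", "first_date"])
        for p in persons:
            for cat in sorted(p.events):
                w.writerow([p.person_id, cat, p.events[cat].isoformat()])
    cov_names = sorted({k for p in persons for k in p.covariates})
    with open(j("covariates.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id"] + cov_names)
        for p in persons:
            w.writerow([p.person_id] + [p.covariates.get(k, "")
                                        for k in cov_names])
    with open(j("outcomes.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "n_hospitalizations", "days_hospitalized"])
        for p in persons:
            w.writerow([p.person_id,
                        p.outcomes.get("n_hospitalizations", ""),
                        p.outcomes.get("days_hospitalized", "")])
    with open(j("truth.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "latent_class"])
        for p in persons:
            w.writerow([p.person_id, p.latent_class or ""])


class CohortParseError(ValueError):
    pass


def _parse_date(s: str, path: str, lineno: int) -> date:
    try:
        return date.fromisoformat(s)
    except ValueError:
        raise CohortParseError(f"{path} line {lineno}: bad date {s!r}") from None


def read_cohort(directory, include_truth: bool = False) -> list[PersonRecord]:
    """Read a cohort written by :func:`write_cohort`; validation failures
    raise :class:`CohortParseError` naming the offending line."""
    import os

    j = lambda name: os.path.join(directory, name)
    persons: dict[str, PersonRecord] = {}
    with open(j("persons.csv"), newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header != _PERSON_HEADER:
            raise CohortParseError("persons.csv: unexpected header")
        for lineno, row in enumerate(r, start=2):
            if not row:
                continue
            if len(row) != len(_PERSON_HEADER):
                raise CohortParseError(f"persons.csv line {lineno}: "
                                       f"expected {len(_PERSON_HEADER)} fields")
            pid, sex, b, c, reason, scz = row
            persons[pid] = PersonRecord(
                person_id=pid, sex=sex,
                birth_date=_parse_date(b, "persons.csv", lineno),
                censor_date=_parse_date(c, "persons.csv", lineno),
                censor_reason=reason,
                scz_first_date=(_parse_date(scz, "persons.csv", lineno)
                                if scz else None))
    with open(j("events.csv"), newline="") as fh:
        r = csv.reader(fh)
        next(r)
        for lineno, row in enumerate(r, start=2):
            if not row:
                continue
            pid, cat, d = row
            if pid not in persons:
                raise CohortParseError(f"events.csv line {lineno}: "
                                       f"unknown person {pid!r}")
            p = persons[pid]
            dd = _parse_date(d, "events.csv", lineno)
            if not (p.birth_date <= dd <= p.censor_date):
                raise CohortParseError(
                    f"events.csv line {lineno}: event date {d} outside "
                    f"[{p.birth_date}, {p.censor_date}]")
            if cat in p.events:
                raise CohortParseError(f"events.csv line {lineno}: duplicate "
                                       f"first diagnosis for {cat}")
            p.events[cat] = dd
    for name, caster in [("covariates.csv", float),
                         ("outcomes.csv", None)]:
        path = j(name)
        if not os.path.exists(path):
            continue
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            cols = next(r)[1:]
            for lineno, row in enumerate(r, start=2):
                if not row:
                    continue
                pid, vals = row[0], row[1:]
                if pid not in persons:
                    raise CohortParseError(f"{name} line {lineno}: unknown "
                                           f"person {pid!r}")
                target = (persons[pid].covariates if name == "covariates.csv"
                          else persons[pid].outcomes)
                for k, v in zip(cols, vals):
                    if v == "":
                        continue
                    if name == "outcomes.csv":
                        target[k] = (int(v) if k == "n_hospitalizations"
                                     else float(v))
                    else:
                        target[k] = float(v)
    if include_truth and os.path.exists(j("truth.csv")):
        with open(j("truth.csv"), newline="") as fh:
            r = csv.reader(fh)
            next(r)
            for row in r:
                if row and row[0] in persons and row[1]:
                    persons[row[0]].latent_class = row[1]
    return list(persons.values())
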