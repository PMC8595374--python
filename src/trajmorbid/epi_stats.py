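"""Registry epidemiology: cumulative incidence under right censoring,
relative risks from 2x2 counts, and time-dependent Cox hazards for
ordered diagnosis pairs.

Cumulative incidence is one minus the Kaplan-Meier survival estimate on
the age scale, censoring at the first of death, emigration, or end of
follow-up (competing risks are handled by censoring, not by a
sub-distribution estimator).  Relative risks use the log-method CI,
``exp(ln RR +/- z * sqrt(1/a - 1/n1 + 1/b - 1/n2))``.  Pairwise hazards
fit, for each ordered category pair (A, B), a Cox model for the first B
diagnosis on the age time scale with sex as a fixed covariate and
"prior A" as a time-varying indicator realized by splitting each
person's follow-up at their first A date.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sequences import DAYS_PER_YEAR

__all__ = [
    "TwoByTwoTable",
    "RiskRatioResult",
    "HazardResult",
    "cumulative_incidence",
    "relative_risk",
    "pairwise_hazards",
    "episode_split",
    "bonferroni",
    "round_sig",
]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposed/unexposed event counts: ``a`` of ``n1`` vs ``b`` of ``n2``."""

    a: int
    n1: int
    b: int
    n2: int

    def __post_init__(self) -> None:
        for x in (self.a, self.n1, self.b, self.n2):
            if not isinstance(x, (int, np.integer)):
                raise TypeError("2x2 counts must be integers")
        if not (0 <= self.a <= self.n1 and 0 <= self.b <= self.n2):
            raise ValueError("counts must satisfy 0 <= events <= totals")


@dataclass
class RiskRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


def relative_risk(table: TwoByTwoTable, alpha: float = 0.05) -> RiskRatioResult:
    """Risk ratio with the log-method confidence interval."""
    a, n1, b, n2 = table.a, table.n1, table.b, table.n2
    if a == 0 or b == 0:
        raise ValueError("zero event cell; consider a continuity correction "
                         "(not applied by default)")
    rr = (a / n1) / (b / n2)
    se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    z = stats.norm.ppf(1 - alpha / 2)
    return RiskRatioResult(rr, rr * math.exp(-z * se), rr * math.exp(z * se),
                           alpha)


def _age_years(start, end) -> float:
    return (end - start).days / DAYS_PER_YEAR


def cumulative_incidence(persons, category: str, at_age: float,
                         split_by_index: bool = False, alpha: float = 0.05):
    """Kaplan-Meier cumulative incidence of a first diagnosis by ``at_age``.

    Returns ``(estimate, ci_low, ci_high)`` or, with ``split_by_index``,
    ``(estimate, ci_low, ci_high, before_fraction)`` where the before/
    after decomposition apportions the overall estimate by the observed
    proportion of first events preceding the index diagnosis.
    """
    from lifelines import KaplanMeierFitter

    durations, events, before = [], [], []
    for p in persons:
        if category in p.events:
            t = _age_years(p.birth_date, p.events[category])
            durations.append(t)
            events.append(1)
            if p.scz_first_date is not None:
                before.append((t, p.events[category] < p.scz_first_date))
        else:
            durations.append(_age_years(p.birth_date, p.censor_date))
            events.append(0)
    durations = np.asarray(durations)
    if len(durations) == 0:
        raise ValueError("no persons supplied")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, events)
    if durations.max() < at_age and \
            float(kmf.survival_function_at_times(durations.max()).iloc[0]) > 0:
        raise ValueError(f"no person remains under observation at age {at_age}")
    est = 1.0 - float(kmf.survival_function_at_times(at_age).iloc[0])
    ci = kmf.confidence_interval_survival_function_
    idx = ci.index.searchsorted(at_age, side="right") - 1
    lo = 1.0 - float(ci.iloc[idx, 1])
    hi = 1.0 - float(ci.iloc[idx, 0])
    if not split_by_index:
        return est, lo, hi
    rel = [b for t, b in before if t <= at_age]
    frac = float(np.mean(rel)) if rel else float("nan")
    return est, lo, hi, frac


def episode_split(persons, first: str, second: str) -> pd.DataFrame:
    """Counting-process rows for the Cox model of ``second`` given prior
    ``first``: follow-up (age scale) split at the first ``first`` date.

    The sum of interval lengths per person equals that person's follow-up
    to the first ``second`` event or censoring, exactly.
    """
    rows = []
    for p in persons:
        t_end = _age_years(p.birth_date, p.censor_date)
        ev = 0
        if second in p.events:
            t_ev = _age_years(p.birth_date, p.events[second])
            if t_ev <= t_end:
                t_end, ev = t_ev, 1
        if t_end <= 0:
            continue
        sex = 1.0 if p.sex == "M" else 0.0
        t_a = (_age_years(p.birth_date, p.events[first])
               if first in p.events else math.inf)
        if 0 < t_a < t_end:
            rows.append((p.person_id, 0.0, t_a, 0, 0.0, sex))
            rows.append((p.person_id, t_a, t_end, ev, 1.0, sex))
        else:
            prior = 1.0 if t_a <= 0 else 0.0
            rows.append((p.person_id, 0.0, t_end, ev, prior, sex))
    return pd.DataFrame(rows, columns=["id", "start", "stop", "event",
                                       "prior", "sex"])


@dataclass
class HazardResult:
    first_category: str
    second_category: str
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    significant_after_bonferroni: bool
    flagged: str = ""


def _fit_pair(df: pd.DataFrame):
    from lifelines import CoxTimeVaryingFitter
    from lifelines.exceptions import ConvergenceError

    exposed = df[df.prior == 1]
    if exposed.empty or exposed.event.sum() == 0:
        return None, "no events among prior-exposed"
    if df["sex"].nunique() < 2:  # constant covariate would be singular
        df = df.drop(columns=["sex"])
    ctv = CoxTimeVaryingFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(df, id_col="id", start_col="start", stop_col="stop",
                    event_col="event", show_progress=False)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        return None, f"non-convergence: {exc}"
    s = ctv.summary.loc["prior"]
    return (float(s["exp(coef)"]), float(s["exp(coef) lower 95%"]),
            float(s["exp(coef) upper 95%"]), float(s["p"])), ""


def pairwise_hazards(persons, categories, alpha: float = 0.05) -> list[HazardResult]:
    """Time-dependent Cox hazard ratios for all ordered category pairs,
    Bonferroni-corrected over ``C * (C - 1)`` tests."""
    categories = list(categories)
    if len(categories) < 2:
        raise ValueError("need at least two categories")
    m = len(categories) * (len(categories) - 1)
    thr = bonferroni(alpha, m)
    out = []
    for first in categories:
        for second in categories:
            if first == second:
                continue
            df = episode_split(persons, first, second)
            res, flag = _fit_pair(df)
            if res is None:
                out.append(HazardResult(first, second, math.nan, math.nan,
                                        math.nan, math.nan, False, flag))
            else:
                hr, lo, hi, p = res
                out.append(HazardResult(first, second, hr, lo, hi, p,
                                        p < thr))
    return out


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be a positive count of tests")
    return alpha / m


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant digits (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)
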