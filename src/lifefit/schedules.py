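"""Survivorship curves and age-specific l_x / m_x schedules.

The cohorts here have no censoring: every individual either dies as a
juvenile on a recorded day or reaches adulthood.  Under no censoring the
Kaplan-Meier estimator reduces exactly to the empirical survival
function, which is what ``km_survivorship`` computes.  ``build_life_table``
turns a cohort into the paired l_x / m_x schedules used for the net
reproductive rate and the Euler-Lotka intrinsic rate: survivorship
follows the cohort curve through the juvenile ages and is held at the
adult plateau across the reproductive window (no adult mortality is
modelled inside the fixed pre-oviposition + oviposition window), and
each adult female spreads her sex-ratio-corrected fecundity uniformly
over the oviposition window starting ``pre_oviposition_days`` after her
emergence.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .records import Cohort, LifeTable

__all__ = [
    "km_survivorship",
    "survival_to_adulthood",
    "build_life_table",
]


def _death_days(cohort: Cohort) -> np.ndarray:
    return np.array(
        [r.event_day for r in cohort.records if r.fate == "died_juvenile"], dtype=int
    )


def km_survivorship(cohort: Cohort) -> Tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier survivorship of the whole cohort.

    With no censoring this equals the empirical survival function
    S(t) = #{individuals alive after day t} / n.  Returns the step
    function as paired arrays ``(days, proportion_surviving)`` with one
    entry for day 0 (S = 1) and one per distinct death day.
    """
    if cohort.n == 0:
        raise ValueError("cannot estimate survivorship of an empty cohort")
    deaths = _death_days(cohort)
    days, counts = np.unique(deaths, return_counts=True)
    surv = 1.0 - np.cumsum(counts) / cohort.n
    return np.concatenate(([0], days)), np.concatenate(([1.0], surv))


def km_at(cohort: Cohort, ages: np.ndarray) -> np.ndarray:
    """Evaluate the no-censoring survival function at integer ages."""
    if cohort.n == 0:
        raise ValueError("cannot estimate survivorship of an empty cohort")
    deaths = _death_days(cohort)
    ages = np.asarray(ages)
    # S(x) = P(death day > x or adult)
    return 1.0 - np.searchsorted(np.sort(deaths), ages, side="right") / cohort.n


def survival_to_adulthood(cohort: Cohort) -> float:
    """Proportion of the cohort reaching adulthood (the terminal KM plateau)."""
    if cohort.n == 0:
        raise ValueError("cannot estimate survival of an empty cohort")
    return sum(r.fate == "adult" for r in cohort.records) / cohort.n


def build_life_table(
    cohort: Cohort,
    pre_oviposition_days: int = 3,
    oviposition_days: int = 6,
    sex_ratio_override: Optional[float] = None,
    survival_mode: str = "curve",
    oviposition_shape: Optional[Sequence[float]] = None,
) -> LifeTable:
    """Construct the l_x / m_x life table of a cohort.

    Each adult female with development time T, fecundity F and offspring
    sex ratio s contributes F/oviposition_days * s daughters per day on
    the ``oviposition_days`` consecutive ages starting at
    T + pre_oviposition_days; m_x averages these contributions over the
    adult females of the cohort.  l_x is the cohort survival curve
    (``survival_mode='curve'``) or the flat terminal survival-to-
    adulthood proportion at every age (``survival_mode='terminal'``, a
    sensitivity switch).  ``sex_ratio_override`` replaces every female's
    own offspring sex ratio by a cohort-level value.
    ``oviposition_shape`` optionally reweights the within-window daily
    laying profile (weights are normalised to sum to 1; default
    uniform).

    Raises ``ValueError`` when the cohort has no reproductive female or
    a female with positive fecundity lacks a sex ratio.
    """
    if oviposition_days < 1:
        raise ValueError("oviposition_days must be >= 1")
    females = cohort.adult_females()
    females = [f for f in females if f.fecundity is not None]
    if not females:
        raise ValueError(
            f"no reproductive females in cohort {cohort.treatment.label}"
        )
    if oviposition_shape is None:
        shape = np.full(oviposition_days, 1.0 / oviposition_days)
    else:
        shape = np.asarray(oviposition_shape, dtype=float)
        if len(shape) != oviposition_days or np.any(shape < 0) or shape.sum() <= 0:
            raise ValueError("oviposition_shape must be oviposition_days non-negative weights")
        shape = shape / shape.sum()

    x_max = max(f.event_day for f in females) + pre_oviposition_days + oviposition_days - 1
    ages = np.arange(x_max + 1)
    mx = np.zeros(x_max + 1)
    for f in females:
        s = sex_ratio_override if sex_ratio_override is not None else f.offspring_sex_ratio
        if f.fecundity == 0:
            continue
        if s is None:
            raise ValueError(
                f"{f.individual_id}: offspring sex ratio missing although fecundity > 0"
            )
        start = f.event_day + pre_oviposition_days
        mx[start : start + oviposition_days] += f.fecundity * s * shape
    mx /= len(females)

    if survival_mode == "curve":
        lx = km_at(cohort, ages)
    elif survival_mode == "terminal":
        p = survival_to_adulthood(cohort)
        lx = np.full(len(ages), p)
        lx[0] = 1.0 if len(ages) else p
        # keep lx non-increasing and anchored at 1 for a newborn cohort
        if len(ages) > 1:
            lx[1:] = p
    else:
        raise ValueError("survival_mode must be 'curve' or 'terminal'")

    return LifeTable(
        ages=ages,
        lx=lx,
        mx=mx,
        pre_oviposition_days=pre_oviposition_days,
        oviposition_days=oviposition_days,
    )
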