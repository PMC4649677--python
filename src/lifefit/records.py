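"""Core domain types for individual life-history records and cohorts.

Age is measured in integer days from entry into observation as a
first-instar larva; events (death, adult emergence) are scored once per
day.  The egg stage is excluded from all schedules, so development time
and every derived rate are comparable across treatments but omit egg
incubation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

STRAINS = ("guava", "eucalyptus")
HOSTS = ("guava", "eucalyptus")
SEXES = ("female", "male", "unknown")
FATES = ("died_juvenile", "adult")

#: Column order of the cohort CSV dialect.
CSV_COLUMNS = (
    "individual_id",
    "strain",
    "host",
    "parent_pair",
    "tree",
    "sex",
    "fate",
    "event_day",
    "pupal_weight",
    "fecundity",
    "offspring_sex_ratio",
)


@dataclass(frozen=True)
class Treatment:
    """A cell of the 2x2 design: insect strain x host-plant diet."""

    strain: str
    host: str

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}; expected one of {STRAINS}")
        if self.host not in HOSTS:
            raise ValueError(f"unknown host {self.host!r}; expected one of {HOSTS}")

    @property
    def label(self) -> str:
        return f"{self.strain}_strain_on_{self.host}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The four treatments of the full factorial design, in a fixed order.
ALL_TREATMENTS = tuple(Treatment(s, h) for s in STRAINS for h in HOSTS)


@dataclass(frozen=True)
class IndividualRecord:
    """One insect's full life history.

    ``event_day`` is the day of death for juveniles that died before
    emergence and the day of adult emergence (development time from
    first instar) for adults.  ``pupal_weight`` is in grams and absent
    for individuals that died before pupation.  ``fecundity`` is total
    eggs laid, present only for adult females; ``offspring_sex_ratio``
    is the proportion of female offspring, present whenever
    fecundity > 0.
    """

    individual_id: str
    strain: str
    host: str
    parent_pair: str
    tree: str
    sex: str
    fate: str
    event_day: int
    pupal_weight: Optional[float] = None
    fecundity: Optional[int] = None
    offspring_sex_ratio: Optional[float] = None

    @property
    def treatment(self) -> Treatment:
        return Treatment(self.strain, self.host)

    @property
    def is_adult_female(self) -> bool:
        return self.fate == "adult" and self.sex == "female"

    @property
    def is_reproductive_female(self) -> bool:
        return (
            self.is_adult_female
            and self.fecundity is not None
            and (self.fecundity == 0 or self.offspring_sex_ratio is not None)
        )


@dataclass
class Cohort:
    """All individuals of one strain x host treatment.

    The cohort is the unit on which survivorship schedules, life tables
    and jackknife resampling operate.
    """

    treatment: Treatment
    records: list[IndividualRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = list(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def without(self, index: int) -> "Cohort":
        """Leave-one-out subcohort (for jackknife resampling)."""
        recs = self.records[:index] + self.records[index + 1 :]
        return Cohort(self.treatment, recs)

    def adult_females(self) -> list[IndividualRecord]:
        return [r for r in self.records if r.is_adult_female]


@dataclass
class LifeTable:
    """Age-indexed survivorship and maternity schedules.

    ``lx`` is the proportion of the original cohort alive at integer age
    ``x`` days; ``mx`` the expected daughters per living female per day.
    ``ages`` starts at 0 (first-instar entry) and increases by one day.
    """

    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    pre_oviposition_days: int = 3
    oviposition_days: int = 6

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.lx = np.asarray(self.lx, dtype=float)
        self.mx = np.asarray(self.mx, dtype=float)
        if not (len(self.ages) == len(self.lx) == len(self.mx)):
            raise ValueError("ages, lx, mx must have equal length")
        if len(self.ages) and self.ages[0] != 0:
            raise ValueError("ages must start at 0")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.lx < -1e-12) or np.any(self.lx > 1 + 1e-12):
            raise ValueError("lx must lie in [0, 1]")
        if np.any(np.diff(self.lx) > 1e-12):
            raise ValueError("lx must be non-increasing")
        if np.any(self.mx < 0):
            raise ValueError("mx must be non-negative")

    @property
    def net_maternity(self) -> np.ndarray:
        """The product l_x * m_x (expected daughters at age x per newborn)."""
        return self.lx * self.mx


@dataclass
class FitnessEstimate:
    """A point estimate of R0 or r_m with jackknife mean, SE and CI."""

    statistic: str  # "R0" | "rm"
    point: float
    jackknife_mean: float
    se: float
    ci_low: float
    ci_high: float
    n_jackknife: int
    alpha: float = 0.05
    treatment: Optional[Treatment] = None

    def __post_init__(self) -> None:
        if self.statistic not in ("R0", "rm"):
            raise ValueError("statistic must be 'R0' or 'rm'")
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if not (self.ci_low - 1e-12 <= self.jackknife_mean <= self.ci_high + 1e-12):
            raise ValueError("jackknife mean must lie inside its CI")


def _validate_record(r: IndividualRecord) -> list[str]:
    v: list[str] = []
    rid = r.individual_id
    if r.strain not in STRAINS:
        v.append(f"{rid}: unknown strain {r.strain!r}")
    if r.host not in HOSTS:
        v.append(f"{rid}: unknown host {r.host!r}")
    if r.sex not in SEXES:
        v.append(f"{rid}: unknown sex {r.sex!r}")
    if r.fate not in FATES:
        v.append(f"{rid}: unknown fate {r.fate!r}")
    if not (isinstance(r.event_day, (int, np.integer)) and r.event_day >= 1):
        v.append(f"{rid}: event_day must be an integer >= 1, got {r.event_day!r}")
    if r.fate == "died_juvenile" and r.fecundity is not None:
        v.append(f"{rid}: fecundity recorded for an individual that died as a juvenile")
    if r.sex == "unknown" and r.fate == "adult":
        v.append(f"{rid}: sex unknown is only permitted for juvenile deaths")
    if r.fecundity is not None:
        if r.sex != "female" or r.fate != "adult":
            v.append(f"{rid}: fecundity present requires an adult female")
        if not (isinstance(r.fecundity, (int, np.integer)) and r.fecundity >= 0):
            v.append(f"{rid}: fecundity must be an integer >= 0, got {r.fecundity!r}")
        if r.fecundity and r.offspring_sex_ratio is None:
            v.append(f"{rid}: offspring_sex_ratio missing although fecundity > 0")
    if r.offspring_sex_ratio is not None and not (0.0 <= r.offspring_sex_ratio <= 1.0):
        v.append(f"{rid}: offspring_sex_ratio must lie in [0, 1]")
    if r.pupal_weight is not None and not r.pupal_weight > 0:
        v.append(f"{rid}: pupal_weight must be > 0 grams")
    return v


def validate_cohort(cohort: Cohort) -> list[str]:
    """Check every record and cohort-level invariant.

    Returns one human-readable entry per violation (empty list when the
    cohort is fully consistent).  Violations are reported, never raised,
    so callers can surface all problems at once.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for r in cohort.records:
        violations.extend(_validate_record(r))
        if (r.strain, r.host) != (cohort.treatment.strain, cohort.treatment.host):
            violations.append(
                f"{r.individual_id}: treatment labels ({r.strain}, {r.host}) differ "
                f"from the cohort's ({cohort.treatment.strain}, {cohort.treatment.host})"
            )
        if r.individual_id in seen:
            violations.append(f"{r.individual_id}: duplicate individual_id in cohort")
        seen.add(r.individual_id)
    return violations
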