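import math

import numpy as np
import pytest
from hypothesis import settings

from lifefit import Cohort, IndividualRecord, Treatment, preset_paper_like

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def make_record():
    """Factory for valid IndividualRecord objects with sensible defaults."""

    def _make(
        i=1,
        strain="guava",
        host="guava",
        sex="female",
        fate="adult",
        day=30,
        weight=0.35,
        fecundity=600,
        sex_ratio=0.5,
    ):
        if fate == "died_juvenile":
            return IndividualRecord(
                individual_id=f"ind-{i}",
                strain=strain,
                host=host,
                parent_pair="p1",
                tree="t1",
                sex=sex,
                fate=fate,
                event_day=day,
            )
        return IndividualRecord(
            individual_id=f"ind-{i}",
            strain=strain,
            host=host,
            parent_pair="p1",
            tree="t1",
            sex=sex,
            fate=fate,
            event_day=day,
            pupal_weight=weight,
            fecundity=fecundity if sex == "female" else None,
            offspring_sex_ratio=(
                sex_ratio if sex == "female" and fecundity else None
            ),
        )

    return _make


@pytest.fixture
def make_cohort(make_record):
    def _make(records, strain="guava", host="guava"):
        return Cohort(Treatment(strain, host), records)

    return _make


@pytest.fixture(scope="session")
def paper_config():
    return preset_paper_like()


def grid_bisection_rm(ages, lxmx, lo=-2.0, hi=4.0, grid=4001, tol=1e-12):
    """Independent Euler-Lotka oracle: coarse grid scan then plain bisection.

    Deliberately naive (no Brent, no analytic bracketing) so it shares no
    code path with lifefit.fitness.intrinsic_rate.
    """
    ages = np.asarray(ages, dtype=float)
    lxmx = np.asarray(lxmx, dtype=float)

    def phi(r):
        return float(np.sum(lxmx * np.exp(-r * ages)) - 1.0)

    rs = np.linspace(lo, hi, grid)
    vals = np.array([phi(r) for r in rs])
    sign = np.sign(vals)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if len(idx) == 0:
        raise AssertionError("oracle found no sign change on the grid")
    a, b = rs[idx[0]], rs[idx[0] + 1]
    fa = phi(a)
    for _ in range(200):
        m = 0.5 * (a + b)
        fm = phi(m)
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
        if b - a < tol:
            break
    return 0.5 * (a + b)
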