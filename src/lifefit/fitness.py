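"""Fitness statistics from life tables.

The net reproductive rate R0 = sum_x l_x m_x is the expected number of
daughters per newborn female over the modelled window.  The intrinsic
rate of increase r_m is the unique real root of the discrete Euler-Lotka
equation

    sum_x exp(-r x) l_x m_x = 1,

solved by bracketed root-finding on the strictly decreasing left-hand
side (ages are exact integer days, matching the daily scoring of the
cohorts).  Per-individual rates give each female her own schedule on top
of the cohort survival, which is what the weight-fitness correlations
use.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .glm import RegressionFit, WeightFecundityGLM
from .records import Cohort, IndividualRecord, LifeTable

__all__ = [
    "net_reproductive_rate",
    "intrinsic_rate",
    "individual_fitness",
    "cohort_individual_rates",
    "fit_weight_fecundity",
    "pearson_correlation",
    "weight_rate_correlation",
]


def net_reproductive_rate(table: LifeTable) -> float:
    """R0 = sum over ages of l_x * m_x (daughters per newborn female)."""
    return float(np.dot(table.lx, table.mx))


def intrinsic_rate(
    table: LifeTable,
    tol: float = 1e-10,
    bracket: Tuple[float, float] = (-1.0, 2.0),
    max_expansions: int = 60,
) -> float:
    """Solve the Euler-Lotka equation for the intrinsic rate r_m (per day).

    phi(r) = sum_x exp(-r x) l_x m_x - 1 is strictly decreasing in r
    whenever reproduction occurs at positive ages, so the root is unique
    and bracketed root-finding (Brent) applies.  The bracket is doubled
    outward when phi has the same sign at both ends.  Requires R0 > 0.
    """
    lxmx = table.net_maternity
    mask = lxmx > 0
    if not np.any(mask):
        raise ValueError("no solution: zero lifetime reproduction (R0 = 0)")
    x = table.ages[mask].astype(float)
    v = lxmx[mask]

    def phi(r: float) -> float:
        return float(np.sum(v * np.exp(-r * x)) - 1.0)

    lo, hi = bracket
    f_lo, f_hi = phi(lo), phi(hi)
    expansions = 0
    # phi decreasing: need phi(lo) > 0 > phi(hi)
    while f_lo < 0 and expansions < max_expansions:
        lo -= (hi - lo)
        f_lo = phi(lo)
        expansions += 1
    while f_hi > 0 and expansions < max_expansions:
        hi += (hi - lo)
        f_hi = phi(hi)
        expansions += 1
    if not (f_lo >= 0 >= f_hi):
        raise ArithmeticError(
            f"could not bracket the Euler-Lotka root after {expansions} expansions "
            f"(phi({lo:.3g}) = {f_lo:.3g}, phi({hi:.3g}) = {f_hi:.3g})"
        )
    root = optimize.brentq(phi, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    if abs(phi(root)) > tol:
        raise ArithmeticError(
            f"Euler-Lotka residual {phi(root):.3g} exceeds tolerance {tol:.3g}"
        )
    return float(root)


def individual_fitness(
    female: IndividualRecord,
    cohort_survival: float,
    pre_oviposition_days: int = 3,
    oviposition_days: int = 6,
) -> Tuple[float, float]:
    """Per-individual (R0_i, rm_i) for one adult female.

    Builds a single-female schedule with l_x equal to the cohort
    survival at every reproductive age, so R0_i = survival * F_i * s_i.
    A female with zero fecundity has R0_i = 0 and an undefined rm_i
    (returned as NaN with a warning); such individuals are excluded from
    weight-rate correlations.
    """
    if not (0.0 < cohort_survival <= 1.0):
        raise ValueError("cohort_survival must lie in (0, 1]")
    if female.fate != "adult" or female.sex != "female" or female.fecundity is None:
        raise ValueError(f"{female.individual_id}: not an adult female with fecundity")
    if female.fecundity == 0:
        warnings.warn(
            f"{female.individual_id}: zero fecundity; r_m undefined (reported as NaN)",
            stacklevel=2,
        )
        return 0.0, float("nan")
    if female.offspring_sex_ratio is None:
        raise ValueError(f"{female.individual_id}: offspring sex ratio missing")

    T = female.event_day
    x_max = T + pre_oviposition_days + oviposition_days - 1
    ages = np.arange(x_max + 1)
    lx = np.where(ages < T, 1.0, cohort_survival)
    lx[0] = 1.0
    mx = np.zeros(x_max + 1)
    daily = female.fecundity * female.offspring_sex_ratio / oviposition_days
    mx[T + pre_oviposition_days :] = daily
    table = LifeTable(
        ages=ages,
        lx=lx,
        mx=mx,
        pre_oviposition_days=pre_oviposition_days,
        oviposition_days=oviposition_days,
    )
    return net_reproductive_rate(table), intrinsic_rate(table)


def cohort_individual_rates(
    cohort: Cohort,
    pre_oviposition_days: int = 3,
    oviposition_days: int = 6,
) -> "pd.DataFrame":
    """Per-female weight, fecundity, R0_i and rm_i for one cohort."""
    import pandas as pd

    from .schedules import survival_to_adulthood

    p = survival_to_adulthood(cohort)
    rows = []
    for f in cohort.adult_females():
        if f.fecundity is None:
            continue
        r0_i, rm_i = individual_fitness(f, p, pre_oviposition_days, oviposition_days)
        rows.append(
            {
                "individual_id": f.individual_id,
                "pupal_weight": f.pupal_weight,
                "fecundity": f.fecundity,
                "R0_i": r0_i,
                "rm_i": rm_i,
            }
        )
    return pd.DataFrame(rows)


def fit_weight_fecundity(
    pairs: Iterable[Tuple[float, float]] | Sequence[Sequence[float]],
) -> RegressionFit:
    """Fit fecundity = exp(a + b * weight) to (weight, fecundity) pairs.

    Thin wrapper around :class:`~lifefit.glm.WeightFecundityGLM`;
    requires at least 3 pairs with at least 2 distinct weights.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (weight, fecundity) tuples")
    model = WeightFecundityGLM().fit(arr[:, 0], arr[:, 1])
    return model.to_fit()


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def weight_rate_correlation(
    weights: Sequence[float],
    rates: Sequence[float],
    method: str = "pearson",
) -> float:
    """Correlation between pupal weight and an individual fitness rate.

    NaN rates (zero-fecundity females, whose r_m is undefined) are
    dropped pairwise with a warning.  ``method`` is ``'pearson'``
    (default) or ``'spearman'`` (rank-based alternative).
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(rates, dtype=float)
    keep = np.isfinite(w) & np.isfinite(r)
    if keep.sum() < len(r):
        warnings.warn(
            f"dropping {int(len(r) - keep.sum())} individuals with undefined rates",
            stacklevel=2,
        )
    w, r = w[keep], r[keep]
    if method == "pearson":
        return pearson_correlation(w, r)
    if method == "spearman":
        if len(w) < 3:
            raise ValueError("need at least 3 observations")
        return float(stats.spearmanr(w, r).statistic)
    raise ValueError("method must be 'pearson' or 'spearman'")
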