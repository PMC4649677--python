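"""Leave-one-out jackknife inference and the CI-overlap comparison rule.

The jackknife recomputes a cohort-level statistic (R0 or r_m) with each
individual left out in turn; pseudo-values
p_i = n * theta - (n - 1) * theta_(-i) give a mean, a standard error
sd(p) / sqrt(n), and a Student-t confidence interval.  Treatments are
declared significantly different when their confidence intervals do not
overlap; compact significance letters summarise all pairwise overlaps.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy import stats

from .records import Cohort, FitnessEstimate

__all__ = [
    "JackknifeResult",
    "jackknife",
    "ci_overlap_significant",
    "letter_groups",
]


@dataclass
class JackknifeResult:
    theta_full: float
    loo_values: List[float]
    pseudo_values: List[float]
    mean: float
    se: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    n: int = 0
    failed_ids: List[str] = field(default_factory=list)

    def to_estimate(self, statistic: str, treatment=None) -> FitnessEstimate:
        return FitnessEstimate(
            statistic=statistic,
            point=self.theta_full,
            jackknife_mean=self.mean,
            se=self.se,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            n_jackknife=self.n,
            alpha=self.alpha,
            treatment=treatment,
        )


def jackknife(
    cohort: Cohort,
    estimator: Callable[[Cohort], float],
    alpha: float = 0.05,
    unit: str = "all",
    ci_method: str = "t",
) -> JackknifeResult:
    """Leave-one-out jackknife of ``estimator`` over cohort individuals.

    ``unit='all'`` (default) leaves out every individual, males and
    juvenile deaths included, since their removal changes the cohort
    survival curve; ``unit='females'`` restricts the resampling to adult
    females.  Subcohorts on which the estimator fails (e.g. the last
    reproductive female removed) are recorded; more than 10% failures is
    an error.  The CI is mean +/- t(1 - alpha/2, n_ok - 1) * se with
    ``ci_method='t'`` (jackknife convention) or a normal quantile with
    ``ci_method='normal'``.
    """
    if unit == "all":
        indices = list(range(cohort.n))
    elif unit == "females":
        indices = [i for i, r in enumerate(cohort.records) if r.is_adult_female]
    else:
        raise ValueError("unit must be 'all' or 'females'")
    n = len(indices)
    if n < 3:
        raise ValueError(f"jackknife needs at least 3 resampling units, got {n}")

    theta_full = float(estimator(cohort))
    loo: List[float] = []
    ok_pseudo: List[float] = []
    failed: List[str] = []
    for i in indices:
        try:
            th = float(estimator(cohort.without(i)))
        except Exception:
            failed.append(cohort.records[i].individual_id)
            loo.append(float("nan"))
            continue
        loo.append(th)
        ok_pseudo.append(n * theta_full - (n - 1) * th)
    if len(failed) > 0.1 * n:
        raise RuntimeError(
            f"estimator failed on {len(failed)}/{n} leave-one-out subcohorts: "
            + ", ".join(failed)
        )

    pv = np.asarray(ok_pseudo, dtype=float)
    n_ok = len(pv)
    mean = float(pv.mean())
    se = float(pv.std(ddof=1) / math.sqrt(n_ok)) if n_ok > 1 else 0.0
    if ci_method == "t":
        q = float(stats.t.ppf(1 - alpha / 2, n_ok - 1))
    elif ci_method == "normal":
        q = float(stats.norm.ppf(1 - alpha / 2))
    else:
        raise ValueError("ci_method must be 't' or 'normal'")
    return JackknifeResult(
        theta_full=theta_full,
        loo_values=loo,
        pseudo_values=list(pv),
        mean=mean,
        se=se,
        ci_low=mean - q * se,
        ci_high=mean + q * se,
        alpha=alpha,
        n=n,
        failed_ids=failed,
    )


def ci_overlap_significant(a: FitnessEstimate, b: FitnessEstimate) -> bool:
    """True iff the two confidence intervals are disjoint.

    Touching endpoints count as overlap (conservative), so equality at a
    boundary is not significant.  Both estimates must carry CIs at the
    same alpha.
    """
    if not math.isclose(a.alpha, b.alpha):
        raise ValueError(f"mismatched alpha: {a.alpha} vs {b.alpha}")
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


def _letters(k: int) -> List[str]:
    out = []
    letters = string.ascii_lowercase
    for i in range(k):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def letter_groups(estimates: Sequence[FitnessEstimate]) -> List[str]:
    """Compact significance letters from pairwise CI overlap.

    Two estimates share a letter iff their confidence intervals overlap
    (the Fig.-5-style display rule).  Implemented as a maximal-clique
    cover of the interval overlap graph: a set of intervals is mutually
    overlapping iff max(ci_low) <= min(ci_high), so maximal cliques are
    found by a sweep over estimates sorted by point value (descending;
    ties broken by treatment label), and each maximal clique receives
    one letter.  The output is invariant to permutation of the input and
    aligned with it.
    """
    m = len(estimates)
    if m < 2:
        raise ValueError("need at least 2 estimates to assign letters")
    if len({e.statistic for e in estimates}) != 1:
        raise ValueError("all estimates must be of the same statistic")

    def sort_key(i: int):
        e = estimates[i]
        lbl = e.treatment.label if e.treatment is not None else ""
        return (-e.point, lbl)

    order = sorted(range(m), key=sort_key)

    rank = {idx: pos for pos, idx in enumerate(order)}
    lows = np.array([e.ci_low for e in estimates])
    highs = np.array([e.ci_high for e in estimates])

    # Every maximal clique of an interval graph is the set of intervals
    # covering some left endpoint, so enumerate cliques at each ci_low,
    # then drop duplicates and non-maximal sets.
    candidates = []
    for p in lows:
        clique = frozenset(np.flatnonzero((lows <= p) & (p <= highs)).tolist())
        if clique not in candidates:
            candidates.append(clique)
    maximal = [c for c in candidates if not any(c < o for o in candidates)]
    maximal.sort(key=lambda c: min(rank[i] for i in c))

    labels = _letters(len(maximal))
    out = ["" for _ in range(m)]
    for lab, clique in zip(labels, maximal):
        for i in clique:
            out[i] += lab
    # Keep each estimate's letters in alphabetical order.
    return ["".join(sorted(s)) for s in out]
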