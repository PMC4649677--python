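"""Scikit-learn-style estimator for cohort-level fitness.

``CohortFitness`` bundles the full per-treatment analysis — survivorship
curve, l_x/m_x life table, R0 and r_m with jackknife confidence
intervals — behind the familiar ``fit`` / fitted-attribute surface, so
it composes with sklearn tooling (``get_params`` / ``set_params``,
``clone``) and reads naturally next to :class:`~lifefit.glm.WeightFecundityGLM`.
"""

from __future__ import annotations

from typing import Optional, Union

import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import io as _io
from .fitness import intrinsic_rate, net_reproductive_rate
from .jackknife import jackknife
from .records import Cohort, validate_cohort
from .schedules import build_life_table, km_survivorship, survival_to_adulthood


class CohortFitness(BaseEstimator):
    """Estimate R0 and r_m (with jackknife CIs) from one cohort.

    Parameters
    ----------
    pre_oviposition_days : int, default 3
        Days between adult emergence and first egg laying.
    oviposition_days : int, default 6
        Length of the egg-laying window (days).
    alpha : float, default 0.05
        Two-sided CI level (0.05 gives 95% intervals).
    jackknife_unit : {'all', 'females'}, default 'all'
        Which individuals are left out in turn.
    sex_ratio_override : float or None
        Cohort-level offspring sex ratio replacing per-female values.
    ci_method : {'t', 'normal'}, default 't'
        Quantile used for the pseudo-value CI.
    survival_mode : {'curve', 'terminal'}, default 'curve'
        Use the full survivorship curve or the flat terminal
        survival-to-adulthood proportion for l_x.

    Attributes
    ----------
    life_table_ : LifeTable
    survival_ : float
        Proportion surviving to adulthood.
    km_days_, km_surv_ : ndarray
        The cohort survivorship step function.
    r0_, rm_ : FitnessEstimate
        Point estimates with jackknife mean, SE and CI.
    n_ : int
        Cohort size.
    """

    def __init__(
        self,
        pre_oviposition_days: int = 3,
        oviposition_days: int = 6,
        alpha: float = 0.05,
        jackknife_unit: str = "all",
        sex_ratio_override: Optional[float] = None,
        ci_method: str = "t",
        survival_mode: str = "curve",
    ):
        self.pre_oviposition_days = pre_oviposition_days
        self.oviposition_days = oviposition_days
        self.alpha = alpha
        self.jackknife_unit = jackknife_unit
        self.sex_ratio_override = sex_ratio_override
        self.ci_method = ci_method
        self.survival_mode = survival_mode

    def _table(self, cohort: Cohort):
        return build_life_table(
            cohort,
            pre_oviposition_days=self.pre_oviposition_days,
            oviposition_days=self.oviposition_days,
            sex_ratio_override=self.sex_ratio_override,
            survival_mode=self.survival_mode,
        )

    def fit(self, X: Union[Cohort, pd.DataFrame], y=None):
        cohort = X if isinstance(X, Cohort) else _io.cohort_from_frame(X)
        problems = validate_cohort(cohort)
        if problems:
            raise ValueError(
                "invalid cohort:\n  " + "\n  ".join(problems[:10])
            )
        self.n_ = cohort.n
        self.km_days_, self.km_surv_ = km_survivorship(cohort)
        self.survival_ = survival_to_adulthood(cohort)
        self.life_table_ = self._table(cohort)

        jk_r0 = jackknife(
            cohort,
            lambda c: net_reproductive_rate(self._table(c)),
            alpha=self.alpha,
            unit=self.jackknife_unit,
            ci_method=self.ci_method,
        )
        jk_rm = jackknife(
            cohort,
            lambda c: intrinsic_rate(self._table(c)),
            alpha=self.alpha,
            unit=self.jackknife_unit,
            ci_method=self.ci_method,
        )
        self.r0_ = jk_r0.to_estimate("R0", cohort.treatment)
        self.rm_ = jk_rm.to_estimate("rm", cohort.treatment)
        self.r0_jackknife_ = jk_r0
        self.rm_jackknife_ = jk_rm
        return self

    def summary(self) -> pd.DataFrame:
        """One row per statistic: point, jackknife mean, SE, CI bounds."""
        check_is_fitted(self, "r0_")
        rows = []
        for est in (self.r0_, self.rm_):
            rows.append(
                {
                    "treatment": est.treatment.label if est.treatment else "",
                    "statistic": est.statistic,
                    "point": est.point,
                    "jk_mean": est.jackknife_mean,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n": est.n_jackknife,
                }
            )
        return pd.DataFrame(rows)
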