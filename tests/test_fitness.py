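"""R0, Euler-Lotka intrinsic rate, per-individual rates, weight-fecundity GLM."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import grid_bisection_rm
from lifefit import (
    LifeTable,
    WeightFecundityGLM,
    fit_weight_fecundity,
    individual_fitness,
    intrinsic_rate,
    net_reproductive_rate,
    pearson_correlation,
    weight_rate_correlation,
)


def pulse_table(age, mass, x_max=None):
    """Schedule with all net maternity concentrated on one day."""
    x_max = x_max or age
    mx = np.zeros(x_max + 1)
    mx[age] = mass
    return LifeTable(ages=np.arange(x_max + 1), lx=np.ones(x_max + 1), mx=mx)


def random_schedule(rng, max_age=80):
    """A random daily schedule with monotone lx and non-trivial maternity."""
    n = rng.integers(15, max_age)
    lx = np.cumprod(1 - rng.uniform(0, 0.05, n))
    lx = np.concatenate(([1.0], lx))
    mx = np.zeros(n + 1)
    start = rng.integers(5, n - 5)
    width = rng.integers(1, min(10, n - start))
    mx[start : start + width] = rng.uniform(0, 3.0, width)
    return LifeTable(ages=np.arange(n + 1), lx=lx, mx=mx)


class TestNetReproductiveRate:
    def test_single_female_full_survival(self, make_record, make_cohort):
        from lifefit import build_life_table

        table = build_life_table(make_cohort([make_record(1, day=30)]))
        assert net_reproductive_rate(table) == pytest.approx(300.0, abs=1e-9)

    def test_zero_maternity_gives_zero(self):
        t = LifeTable(ages=np.arange(5), lx=np.ones(5), mx=np.zeros(5))
        assert net_reproductive_rate(t) == 0.0

    def test_constant_survival_factorizes(self, make_record, make_cohort):
        from lifefit import build_life_table

        cohort = make_cohort([make_record(1, day=30)])
        table = build_life_table(cohort, survival_mode="terminal")
        table.lx[:] = 0.25
        assert net_reproductive_rate(table) == pytest.approx(0.25 * 300.0)


class TestIntrinsicRate:
    def test_r0_of_one_gives_rm_zero(self):
        table = pulse_table(12, 1.0)
        assert intrinsic_rate(table) == pytest.approx(0.0, abs=1e-10)

    def test_single_pulse_closed_form(self):
        table = pulse_table(10, 2.0)
        assert intrinsic_rate(table) == pytest.approx(math.log(2) / 10, abs=1e-8)

    def test_two_point_schedule_matches_bisection_oracle(self):
        mx = np.zeros(21)
        mx[10] = mx[20] = 1.0
        table = LifeTable(ages=np.arange(21), lx=np.ones(21), mx=mx)
        rm = intrinsic_rate(table)
        oracle = grid_bisection_rm(table.ages, table.net_maternity)
        assert rm == pytest.approx(oracle, abs=1e-8)

    def test_zero_reproduction_is_an_error(self):
        t = LifeTable(ages=np.arange(5), lx=np.ones(5), mx=np.zeros(5))
        with pytest.raises(ValueError, match="zero lifetime reproduction"):
            intrinsic_rate(t)

    def test_bracket_auto_expansion(self):
        # very fast growth: rm far above the default bracket's upper end
        table = pulse_table(1, 5e6)
        rm = intrinsic_rate(table, bracket=(-0.01, 0.01))
        assert rm == pytest.approx(math.log(5e6), abs=1e-6)

    @given(seed=st.integers(0, 10_000))
    def test_sign_linkage_with_r0(self, seed):
        """rm > 0 iff R0 > 1, rm < 0 iff R0 < 1 (random schedules)."""
        rng = np.random.default_rng(seed)
        table = random_schedule(rng)
        r0 = net_reproductive_rate(table)
        if r0 <= 0:
            return
        rm = intrinsic_rate(table)
        if abs(r0 - 1) < 1e-9:
            assert abs(rm) < 1e-8
        else:
            assert (rm > 0) == (r0 > 1)

    @given(seed=st.integers(0, 10_000))
    def test_log_r0_bounds(self, seed):
        """ln(R0)/x_last <= rm <= ln(R0)/x_first for growing schedules."""
        rng = np.random.default_rng(seed)
        table = random_schedule(rng)
        r0 = net_reproductive_rate(table)
        if r0 <= 1.0:
            return
        rm = intrinsic_rate(table)
        active = np.flatnonzero(table.net_maternity > 0)
        x_first, x_last = table.ages[active[0]], table.ages[active[-1]]
        assert math.log(r0) / x_last - 1e-10 <= rm <= math.log(r0) / x_first + 1e-10

    @given(seed=st.integers(0, 10_000), delay=st.integers(1, 15))
    def test_delaying_reproduction_preserves_r0_and_lowers_rm(self, seed, delay):
        # survivorship held flat across the window, as in the cohort life
        # tables, so delaying maternity moves timing but not lifetime output
        rng = np.random.default_rng(seed)
        table = random_schedule(rng)
        table = LifeTable(ages=table.ages, lx=np.ones_like(table.lx), mx=table.mx)
        r0 = net_reproductive_rate(table)
        if r0 <= 1.0 + 1e-9:
            return
        n = len(table.ages)
        shifted = LifeTable(
            ages=np.arange(n + delay),
            lx=np.ones(n + delay),
            mx=np.concatenate((np.zeros(delay), table.mx)),
        )
        assert net_reproductive_rate(shifted) == pytest.approx(r0, rel=1e-12)
        assert intrinsic_rate(shifted) < intrinsic_rate(table)


class TestIndividualFitness:
    def test_full_survival_closed_form(self, make_record):
        r0, rm = individual_fitness(make_record(1, day=30), cohort_survival=1.0)
        assert r0 == pytest.approx(300.0, abs=1e-9)
        assert rm > 0

    def test_r0_linear_in_survival(self, make_record):
        r0_half, _ = individual_fitness(make_record(1, day=30), cohort_survival=0.5)
        assert r0_half == pytest.approx(150.0, abs=1e-9)

    def test_zero_fecundity_undefined_rm(self, make_record):
        rec = make_record(1, fecundity=0)
        with pytest.warns(UserWarning, match="undefined"):
            r0, rm = individual_fitness(rec, cohort_survival=1.0)
        assert r0 == 0.0 and math.isnan(rm)

    def test_rejects_non_female(self, make_record):
        with pytest.raises(ValueError, match="adult female"):
            individual_fitness(make_record(1, sex="male"), cohort_survival=1.0)


class TestWeightFecundityGLM:
    def test_flat_response_recovers_log_mean(self):
        fit = fit_weight_fecundity([(0.2, 400), (0.3, 400), (0.4, 400)])
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert fit.intercept == pytest.approx(math.log(400), abs=1e-8)

    def test_noiseless_exponential_recovery(self):
        w = np.linspace(0.1, 1.0, 40)
        y = np.round(np.exp(2 + 3 * w))
        fit = fit_weight_fecundity(list(zip(w, y)))
        assert fit.intercept == pytest.approx(2.0, abs=0.05)
        assert fit.slope == pytest.approx(3.0, abs=0.05)
        assert fit.deviance_explained > 0.99

    def test_identical_weights_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_weight_fecundity([(0.3, 10), (0.3, 20), (0.3, 30)])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_weight_fecundity([(0.3, 10), (0.4, 20)])

    def test_matches_statsmodels_quasipoisson(self):
        """Independent oracle: statsmodels GLM with Pearson-scaled covariance."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        w = rng.uniform(0.2, 0.55, 300)
        y = rng.poisson(np.exp(5.0 + 2.0 * w))
        model = WeightFecundityGLM().fit(w, y)
        X = sm.add_constant(w)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
        assert model.intercept_ == pytest.approx(ref.params[0], abs=1e-6)
        assert model.slope_ == pytest.approx(ref.params[1], abs=1e-6)
        assert model.se_intercept_ == pytest.approx(ref.bse[0], rel=1e-4)
        assert model.se_slope_ == pytest.approx(ref.bse[1], rel=1e-4)
        assert model.dispersion_ == pytest.approx(ref.scale, rel=1e-6)

    def test_estimates_converge_with_n(self):
        """Bias at n = 2000 is below 2 reported SEs for known (a, b)."""
        rng = np.random.default_rng(12)
        w = rng.uniform(0.2, 0.55, 2000)
        y = rng.poisson(np.exp(5.95 + 2.37 * w))
        fit = fit_weight_fecundity(list(zip(w, y)))
        assert abs(fit.intercept - 5.95) < 2 * fit.se_intercept
        assert abs(fit.slope - 2.37) < 2 * fit.se_slope

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        model = WeightFecundityGLM(max_iter=50, tol=1e-8)
        assert clone(model).get_params() == model.get_params()

    def test_predict_is_exp_of_linear_predictor(self):
        w = np.linspace(0.1, 1.0, 30)
        y = np.round(np.exp(1 + 2 * w))
        model = WeightFecundityGLM().fit(w, y)
        np.testing.assert_allclose(
            model.predict([0.5]), [math.exp(model.intercept_ + 0.5 * model.slope_)]
        )


class TestCorrelations:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),
            ([1, 2, 3], [-1, -2, -3], -1.0),
            ([1, 2, 3], [1, 3, 2], 0.5),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_nan_rates_dropped_with_warning(self):
        w = [0.2, 0.3, 0.4, 0.5, 0.6]
        r = [1.0, 2.0, float("nan"), 3.0, 4.0]
        with pytest.warns(UserWarning, match="undefined"):
            rho = weight_rate_correlation(w, r)
        assert rho == pytest.approx(pearson_correlation([0.2, 0.3, 0.5, 0.6], [1, 2, 3, 4]))

    def test_spearman_option(self):
        w = [0.2, 0.3, 0.4, 0.5]
        r = [1.0, 10.0, 100.0, 1000.0]  # monotone, nonlinear
        assert weight_rate_correlation(w, r, method="spearman") == pytest.approx(1.0)
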