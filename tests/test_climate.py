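"""Bias correction, monthly aggregation, BIOCLIM variables and chilling hours."""

import numpy as np
import pytest

import invasim as iv
from invasim.climate import BIO_NAMES, DailyClimate, days_in_year, month_lengths

from conftest import small_grid


def make_daily(grid, years, tmax_fn, tmin_fn, prcp_fn):
    """Build a DailyClimate from per-day scalar (or array) functions."""
    dc = DailyClimate(grid)
    for y in years:
        nd = days_in_year(y)
        shape = (nd,) + grid.shape
        tmax = np.broadcast_to(np.asarray([tmax_fn(y, d) for d in range(nd)],
                                          dtype=float)[:, None, None], shape)
        tmin = np.broadcast_to(np.asarray([tmin_fn(y, d) for d in range(nd)],
                                          dtype=float)[:, None, None], shape)
        prcp = np.broadcast_to(np.asarray([prcp_fn(y, d) for d in range(nd)],
                                          dtype=float)[:, None, None], shape)
        dc.add_year(y, tmax.copy(), tmin.copy(), prcp.copy())
    return dc


# ---------------------------------------------------------------- monthly

class TestDailyToMonthly:
    def test_constants_and_sums(self, grid10):
        dc = make_daily(grid10, [2019], lambda y, d: 10.0, lambda y, d: 4.0,
                        lambda y, d: 1.0)
        m = iv.daily_to_monthly(dc)
        np.testing.assert_allclose(m.tmax_mean[2019], 10.0)
        np.testing.assert_allclose(m.tmin_mean[2019], 4.0)
        # April has 30 days of 1 mm/day
        np.testing.assert_allclose(m.prcp_total[2019][3], 30.0)

    def test_leap_february(self, grid10):
        dc = make_daily(grid10, [2020], lambda y, d: 5.0, lambda y, d: 0.0,
                        lambda y, d: 2.0)
        m = iv.daily_to_monthly(dc)
        np.testing.assert_allclose(m.prcp_total[2020][1], 58.0)  # 29 days x 2 mm


# ---------------------------------------------------------------- linear scaling

class TestLinearScaling:
    def test_identity_when_model_equals_obs(self, grid10):
        dc = make_daily(grid10, [2000, 2001], lambda y, d: 15.0 + d % 7,
                        lambda y, d: 5.0, lambda y, d: 2.0)
        out = iv.linear_scaling(dc, dc, [2000, 2001])
        for y in (2000, 2001):
            np.testing.assert_allclose(out.tmax[y], dc.tmax[y], atol=1e-12)
            np.testing.assert_allclose(out.prcp[y], dc.prcp[y], atol=1e-12)

    def test_additive_shift_and_precip_ratio(self, grid10):
        model = make_daily(grid10, [2000], lambda y, d: 12.0, lambda y, d: 2.0,
                           lambda y, d: 1.0)
        obs = make_daily(grid10, [2000], lambda y, d: 10.0, lambda y, d: 0.0,
                         lambda y, d: 2.0)
        out = iv.linear_scaling(model, obs, [2000])
        np.testing.assert_allclose(out.tmax[2000], 10.0)   # -2 degC everywhere
        np.testing.assert_allclose(out.prcp[2000], 2.0)    # doubled

    def test_full_overlap_matches_observed_monthly_means(self, grid10):
        rng = np.random.default_rng(5)
        years = [2000, 2001]

        def rand_daily(seed):
            r = np.random.default_rng(seed)
            tmax = {(y, d): 10 + 5 * r.standard_normal()
                    for y in years for d in range(days_in_year(y))}
            return make_daily(grid10, years,
                              lambda y, d: tmax[y, d],
                              lambda y, d: tmax[y, d] - r.uniform(1, 10),
                              lambda y, d: r.gamma(2.0))

        model, obs = rand_daily(1), rand_daily(2)
        out = iv.linear_scaling(model, obs, years)
        mo, mm = iv.daily_to_monthly(obs), iv.daily_to_monthly(out)
        t_obs = np.mean([mo.tmax_mean[y] for y in years], axis=0)
        t_cor = np.mean([mm.tmax_mean[y] for y in years], axis=0)
        np.testing.assert_allclose(t_cor, t_obs, atol=1e-9)
        p_obs = np.mean([mo.prcp_total[y] for y in years], axis=0)
        p_cor = np.mean([mm.prcp_total[y] for y in years], axis=0)
        np.testing.assert_allclose(p_cor, p_obs, rtol=1e-6)

    def test_empty_overlap_error(self, grid10):
        dc = make_daily(grid10, [2000], lambda y, d: 5.0, lambda y, d: 0.0,
                        lambda y, d: 1.0)
        with pytest.raises(ValueError, match="overlap"):
            iv.linear_scaling(dc, dc, [])


# ---------------------------------------------------------------- biovars

def biovars_bruteforce(tmax, tmin, prcp):
    """Independent exhaustive-quarter oracle for the 19 BIOCLIM variables.

    Scalar-month implementation: enumerates all 12 wrapped quarters
    explicitly and loops rather than vectorizing.
    """
    tmean = [(a + b) / 2 for a, b in zip(tmax, tmin)]
    quarters = [[(m + k) % 12 for k in range(3)] for m in range(12)]
    qtemp = [sum(tmean[i] for i in q) / 3 for q in quarters]
    qprcp = [sum(prcp[i] for i in q) for q in quarters]

    def argbest(vals, best):
        target = best(vals)
        return min(i for i, v in enumerate(vals) if v == target)

    wet, dry = argbest(qprcp, max), argbest(qprcp, min)
    warm, cold = argbest(qtemp, max), argbest(qtemp, min)
    out = {}
    out["BIO1"] = float(np.mean(tmean))
    out["BIO2"] = float(np.mean([a - b for a, b in zip(tmax, tmin)]))
    out["BIO4"] = 100.0 * float(np.std(tmean))
    out["BIO5"] = max(tmax)
    out["BIO6"] = min(tmin)
    out["BIO7"] = out["BIO5"] - out["BIO6"]
    out["BIO3"] = 100.0 * out["BIO2"] / out["BIO7"] if out["BIO7"] > 0 else 0.0
    out["BIO8"], out["BIO9"] = qtemp[wet], qtemp[dry]
    out["BIO10"], out["BIO11"] = qtemp[warm], qtemp[cold]
    out["BIO12"] = float(sum(prcp))
    out["BIO13"], out["BIO14"] = max(prcp), min(prcp)
    out["BIO15"] = 100.0 * float(np.std(prcp)) / (1.0 + float(np.mean(prcp)))
    out["BIO16"], out["BIO17"] = qprcp[wet], qprcp[dry]
    out["BIO18"], out["BIO19"] = qprcp[warm], qprcp[cold]
    return out


def monthly_from_arrays(grid, year, tmax, tmin, prcp):
    m = iv.MonthlyClimate(grid)
    shape = (12,) + grid.shape
    m.tmax_mean[year] = np.broadcast_to(np.asarray(tmax)[:, None, None], shape).copy()
    m.tmin_mean[year] = np.broadcast_to(np.asarray(tmin)[:, None, None], shape).copy()
    m.prcp_total[year] = np.broadcast_to(np.asarray(prcp)[:, None, None], shape).copy()
    return m


class TestBiovars:
    def test_constant_climate(self):
        g = small_grid(2)
        m = monthly_from_arrays(g, 2020, [10.0] * 12, [10.0] * 12, [50.0] * 12)
        b = iv.biovars(m, 2020)
        for name, val in [("BIO1", 10), ("BIO4", 0), ("BIO7", 0), ("BIO12", 600),
                          ("BIO13", 50), ("BIO14", 50), ("BIO15", 0)]:
            np.testing.assert_allclose(b[name].values, val, atol=1e-12)

    def test_linear_monthly_means(self):
        g = small_grid(2)
        months = np.arange(1.0, 13.0)
        m = monthly_from_arrays(g, 2020, months, months, np.ones(12))
        np.testing.assert_allclose(iv.biovars(m, 2020)["BIO1"].values, 6.5)

    def test_matches_bruteforce_oracle_on_200_random_inputs(self):
        g = small_grid(1)
        rng = np.random.default_rng(42)
        for trial in range(200):
            tmin = rng.uniform(-20, 20, 12)
            tmax = tmin + rng.uniform(0, 15, 12)
            prcp = np.round(rng.gamma(2, 30, 12), 3)
            m = monthly_from_arrays(g, 2020, tmax, tmin, prcp)
            got = iv.biovars(m, 2020)
            want = biovars_bruteforce(list(tmax), list(tmin), list(prcp))
            for name in BIO_NAMES:
                np.testing.assert_allclose(got[name].values[0, 0], want[name],
                                           rtol=1e-12, atol=1e-10, err_msg=name)

    def test_bioclim_internal_inequalities(self):
        g = small_grid(1)
        rng = np.random.default_rng(9)
        tmin = rng.uniform(-10, 10, 12)
        m = monthly_from_arrays(g, 2020, tmin + rng.uniform(0, 10, 12), tmin,
                                rng.gamma(2, 30, 12))
        b = iv.biovars(m, 2020)
        assert b["BIO5"].values[0, 0] >= b["BIO6"].values[0, 0]
        assert b["BIO13"].values[0, 0] >= b["BIO14"].values[0, 0]
        np.testing.assert_allclose(b["BIO7"].values, b["BIO5"].values - b["BIO6"].values)


class TestLongTermMean:
    def _sets(self, grid, bio1_values):
        sets = []
        for i, v in enumerate(bio1_values):
            m = monthly_from_arrays(grid, 1991 + i, [v] * 12, [v] * 12, [10.0] * 12)
            sets.append(iv.biovars(m, 1991 + i))
        return sets

    def test_identical_years(self):
        g = small_grid(2)
        sets = self._sets(g, [7.0] * 30)
        bcl = iv.long_term_mean(sets, window=30)
        assert bcl.label == "BCL_2020"
        np.testing.assert_allclose(bcl["BIO1"].values, 7.0)

    def test_arithmetic_sequence(self):
        g = small_grid(2)
        bcl = iv.long_term_mean(self._sets(g, list(range(30))), window=30)
        np.testing.assert_allclose(bcl["BIO1"].values, 14.5)

    def test_window_one_and_short_error(self):
        g = small_grid(2)
        sets = self._sets(g, [3.0, 4.0])
        np.testing.assert_allclose(iv.long_term_mean(sets, window=1)["BIO1"].values, 4.0)
        with pytest.raises(ValueError, match="at least"):
            iv.long_term_mean(sets, window=3)


# ---------------------------------------------------------------- hourly / ACH

class TestDailyToHourly:
    def test_zero_amplitude(self):
        np.testing.assert_allclose(iv.daily_to_hourly(2.0, 2.0), 2.0)

    def test_mean_and_extrema_hours(self):
        h = iv.daily_to_hourly(0.0, 10.0)
        np.testing.assert_allclose(h.mean(), 5.0, atol=1e-12)
        assert h[5] == pytest.approx(0.0) and h[17] == pytest.approx(10.0)
        assert h.min() == pytest.approx(0.0) and h.max() == pytest.approx(10.0)
        assert np.argmin(h) == 5 and np.argmax(h) == 17

    def test_tmin_above_tmax_error(self):
        with pytest.raises(ValueError, match="tmin"):
            iv.daily_to_hourly(5.0, 1.0)


class TestChillingHours:
    def test_constant_two_degrees_fills_window(self, grid10):
        dc = make_daily(grid10, [2021], lambda y, d: 2.0, lambda y, d: 2.0,
                        lambda y, d: 0.0)
        ach = iv.accumulated_chilling_hours(dc, 2021)
        np.testing.assert_allclose(ach.values, 24 * (90 - 32 + 1))  # 1416

    def test_frozen_hours_do_not_count(self, grid10):
        dc = make_daily(grid10, [2021], lambda y, d: -10.0, lambda y, d: -10.0,
                        lambda y, d: 0.0)
        np.testing.assert_allclose(iv.accumulated_chilling_hours(dc, 2021).values, 0.0)

    def test_thirty_chilling_days_give_720_hours(self, grid10):
        # 30 days at 2 degC inside the window, hot otherwise: the documented
        # dormancy-break threshold equals 30 full chilling days
        chill_days = set(range(32, 62))
        dc = make_daily(grid10, [2021],
                        lambda y, d: 2.0 if (d + 1) in chill_days else 30.0,
                        lambda y, d: 2.0 if (d + 1) in chill_days else 30.0,
                        lambda y, d: 0.0)
        np.testing.assert_allclose(iv.accumulated_chilling_hours(dc, 2021).values, 720.0)

    def test_day_permutation_invariance_and_monotonicity(self, grid10):
        rng = np.random.default_rng(3)
        temps = rng.uniform(-5, 10, 365)
        perm = temps.copy()
        window = slice(31, 90)
        perm[window] = rng.permutation(perm[window])
        dc1 = make_daily(grid10, [2021], lambda y, d: temps[d], lambda y, d: temps[d],
                         lambda y, d: 0.0)
        dc2 = make_daily(grid10, [2021], lambda y, d: perm[d], lambda y, d: perm[d],
                         lambda y, d: 0.0)
        a1 = iv.accumulated_chilling_hours(dc1, 2021)
        a2 = iv.accumulated_chilling_hours(dc2, 2021)
        np.testing.assert_allclose(a1.values, a2.values)
        # turning one non-chilling day into a chilling day never decreases ACH
        temps2 = temps.copy()
        temps2[40] = 3.0
        dc3 = make_daily(grid10, [2021], lambda y, d: temps2[d], lambda y, d: temps2[d],
                         lambda y, d: 0.0)
        assert (iv.accumulated_chilling_hours(dc3, 2021).values >= a1.values).all()

    def test_window_outside_year_error(self, grid10):
        dc = make_daily(grid10, [2021], lambda y, d: 2.0, lambda y, d: 2.0,
                        lambda y, d: 0.0)
        with pytest.raises(ValueError, match="window"):
            iv.accumulated_chilling_hours(dc, 2021, doy_start=300, doy_end=400)
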