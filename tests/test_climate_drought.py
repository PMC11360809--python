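"""Thornthwaite PET, SPEI standardization and drought classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from droughtring.climate_drought import (ClimateSeries, DroughtCalendar, SpeiSeries,
                                         classify_drought, drought_year_summary,
                                         spei, standard_normal_quantile,
                                         thornthwaite_pet, _day_length_correction)
from droughtring.synthetic_data import (SimulationConfig, gen_climate,
                                        load_table1_fixture)


def make_climate(tmean_by_month, prec_by_month, years=range(1972, 2021),
                 latitude=47.0, site="X"):
    rows = [{"year": y, "month": m, "tmean": tmean_by_month[m - 1],
             "prec": prec_by_month[m - 1]} for y in years for m in range(1, 13)]
    return ClimateSeries(site_id=site, latitude=latitude, data=pd.DataFrame(rows))


class TestThornthwaite:
    def test_all_cold_months_give_zero_pet(self):
        clim = thornthwaite_pet(make_climate([-5.0] * 12, [50.0] * 12))
        assert (clim.data["pet"] == 0).all()

    def test_equatorial_correction_near_one(self):
        k = _day_length_correction(0.0)
        # at the equator day length is 12 h; K deviates only via month length
        np.testing.assert_allclose(k, np.array(
            [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]) / 30.0, rtol=1e-12)
        assert np.all(np.abs(k[[3, 5, 8, 10]] - 1.0) < 0.03)  # 30-day months

    def test_hand_computed_closed_form(self):
        """t = 10 C all year at latitude 0: PET from the hand-evaluated formula.

        I = 12*(2)**1.514 = 34.27210, a = 1.043158, e = 16*(100/I)**a
        = 48.89343 mm / 30-day month.
        """
        clim = thornthwaite_pet(make_climate([10.0] * 12, [50.0] * 12, latitude=0.0))
        jan = clim.data[(clim.data.year == 1972) & (clim.data.month == 1)].pet.iloc[0]
        apr = clim.data[(clim.data.year == 1972) & (clim.data.month == 4)].pet.iloc[0]
        assert jan == pytest.approx(48.89343186856465 * 31 / 30, abs=0.1)
        assert apr == pytest.approx(48.89343186856465, abs=0.1)

    def test_pet_nonnegative_and_increasing_in_t(self, small_sim):
        _, climate, _, _ = small_sim
        clim = thornthwaite_pet(climate)
        assert (clim.data["pet"] >= 0).all()
        warm = clim.data[(clim.data.tmean > 0) & (clim.data.tmean < 26.5)]
        for year, grp in warm.groupby("year"):
            g = grp.sort_values("tmean")
            # unadjusted PET (pet / K) must rise with temperature within a year
            k = _day_length_correction(clim.latitude)[g["month"].to_numpy() - 1]
            unadj = g["pet"].to_numpy() / k
            assert np.all(np.diff(unadj) >= -1e-9)

    def test_annual_summaries_consistent(self, small_sim):
        _, climate, _, _ = small_sim
        ann = climate.annual_summary()
        one = climate.data[climate.data.year == ann.year.iloc[0]]
        assert ann.ap.iloc[0] == pytest.approx(one.prec.sum(), abs=1e-9)
        assert ann.mat.iloc[0] == pytest.approx(one.tmean.mean(), abs=1e-9)

    def test_incomplete_year_rejected(self):
        rows = [{"year": 2000, "month": m, "tmean": 5.0, "prec": 50.0}
                for m in range(1, 12)]
        with pytest.raises(Exception, match="complete"):
            ClimateSeries(site_id="x", latitude=45, data=pd.DataFrame(rows))


@pytest.fixture(scope="module")
def synthetic_spei():
    cfg = SimulationConfig(seed=101)
    climate = thornthwaite_pet(gen_climate(cfg))
    return climate, spei(climate, scale=3)


class TestSpei:
    def test_per_month_standardization(self, synthetic_spei):
        """Per calendar month over the calibration period: mean ~ 0, sd ~ 1."""
        _, sp = synthetic_spei
        for m in range(1, 13):
            v = sp.month_values(m)
            assert abs(v.mean()) < 0.05
            assert abs(v.std(ddof=1) - 1) < 0.1

    def test_first_scale_minus_one_months_undefined(self, synthetic_spei):
        _, sp = synthetic_spei
        head = sp.data.sort_values(["year", "month"]).head(3)
        assert head["spei"].isna().sum() == 2

    def test_minimum_balance_maps_to_minimum_spei(self, synthetic_spei):
        climate, sp = synthetic_spei
        d = climate.data["balance"].to_numpy()
        rolled = pd.Series(d).rolling(3).sum().to_numpy()
        months = climate.data["month"].to_numpy()
        vals = sp.data["spei"].to_numpy()
        for m in (6, 8, 12):
            sel = (months == m) & np.isfinite(rolled)
            assert np.argmin(rolled[sel]) == np.nanargmin(vals[sel])

    def test_location_shift_invariance(self, synthetic_spei):
        """Adding a constant to every monthly balance leaves SPEI unchanged."""
        climate, sp = synthetic_spei
        shifted = ClimateSeries(site_id=climate.site_id, latitude=climate.latitude,
                                data=climate.data.assign(
                                    balance=climate.data["balance"] + 123.4))
        sp2 = spei(shifted, scale=3)
        np.testing.assert_allclose(sp2.data["spei"], sp.data["spei"], atol=1e-7)

    def test_against_numerical_ml_oracle(self, synthetic_spei):
        """PWM-fitted SPEI vs an independent maximum-likelihood fit.

        The oracle fits the same generalized-logistic family by direct
        numerical ML (Nelder-Mead on the negative log-likelihood) and
        recomputes SPEI; 95% of months must agree within 0.15.
        """
        climate, sp = synthetic_spei
        d = climate.data["balance"].to_numpy()
        rolled = pd.Series(d).rolling(3).sum().to_numpy()
        months = climate.data["month"].to_numpy()
        diffs = []
        for m in range(1, 13):
            x = rolled[(months == m) & np.isfinite(rolled)]

            def nll(theta):
                xi, log_alpha, k = theta
                alpha = np.exp(log_alpha)
                z = (x - xi) / alpha
                arg = 1 - k * z
                if np.any(arg <= 0):
                    return 1e10
                y = -np.log(arg) / k if abs(k) > 1e-9 else z
                return float(np.sum(np.log(alpha) + (1 - k) * y
                                    + 2 * np.log1p(np.exp(-y))))

            start = np.array([np.median(x), np.log(x.std() * 0.55), -0.01])
            res = optimize.minimize(nll, start, method="Nelder-Mead",
                                    options={"maxiter": 4000, "xatol": 1e-8,
                                             "fatol": 1e-8})
            xi, log_alpha, k = res.x
            alpha = np.exp(log_alpha)
            z = (x - xi) / alpha
            y = -np.log(np.maximum(1 - k * z, 1e-12)) / k
            f = 1 / (1 + np.exp(-y))
            oracle = stats.norm.ppf(np.clip(f, 1e-9, 1 - 1e-9))
            mine = sp.month_values(m).to_numpy()
            diffs.extend(np.abs(oracle - mine))
        diffs = np.asarray(diffs)
        assert np.mean(diffs <= 0.15) >= 0.95

    def test_short_record_rejected(self):
        clim = make_climate([10.0] * 12, [60.0] * 12, years=range(2000, 2015))
        with pytest.raises(Exception, match="20 years"):
            spei(thornthwaite_pet(clim), 3)

    def test_normal_quantile_approximation(self):
        p = np.linspace(0.001, 0.999, 201)
        assert np.abs(standard_normal_quantile(p) - stats.norm.ppf(p)).max() < 5e-4


class TestClassification:
    def make_spei(self, values):
        df = pd.DataFrame({"year": 2000, "month": np.arange(1, len(values) + 1),
                           "spei": values})
        return SpeiSeries(site_id="x", scale=3, data=df)

    @pytest.mark.parametrize("value,expected", [
        (-1.0, "moderate"), (-1.2, "moderate"), (-1.49, "moderate"),
        (-1.5, "severe"), (-1.7, "severe"), (-1.99, "severe"),
        (-2.0, "extreme"), (-2.5, "extreme"),
    ])
    def test_band_boundaries(self, value, expected):
        cal = classify_drought(self.make_spei([value]))
        assert list(cal.entries["severity"]) == [expected]

    def test_above_moderate_unclassified(self):
        cal = classify_drought(self.make_spei([-0.99, 0.5, 2.0]))
        assert cal.entries.empty

    def test_classes_partition(self, synthetic_spei):
        _, sp = synthetic_spei
        cal = classify_drought(sp)
        merged = cal.entries.merge(sp.data, on=["year", "month"])
        assert (merged["spei"] <= -1.0).all()
        assert not merged.duplicated(["year", "month"]).any()
        n_dry = int((sp.data["spei"] <= -1.0).sum())
        assert len(cal.entries) == n_dry

    def test_empty_calendar_summary(self):
        cal = DroughtCalendar(site_id="x")
        s = drought_year_summary(cal)
        row = s["per_site"].iloc[0]
        assert row.n_years_severe_or_extreme == 0 and row.n_years_extreme == 0


@pytest.fixture(scope="module")
def calendars():
    return load_table1_fixture()


class TestPublishedCalendar:
    """Checks against the packaged transcription of the published drought calendar."""

    def test_severe_extreme_year_counts(self, calendars):
        counts = {site: len(cal.severe_or_extreme_years())
                  for site, cal in calendars.items()}
        assert counts == {"Dorna Candrenilor": 23, "Turda": 23, "Zarnesti": 24}

    def test_extreme_year_counts(self, calendars):
        assert len(calendars["Dorna Candrenilor"].extreme_years()) == 5
        assert len(calendars["Turda"].extreme_years()) == 3

    def test_common_extreme_years(self, calendars):
        s = drought_year_summary(calendars.values())
        assert s["common_extreme_years"] == [2000, 2003]

    def test_specific_entries(self, calendars):
        dorna = calendars["Dorna Candrenilor"].entries
        e2000 = dorna[(dorna.year == 2000) & (dorna.severity == "extreme")]
        assert sorted(e2000.month) == [6, 12]
        zarn = calendars["Zarnesti"].entries
        assert (zarn.year != 1973).all()
        turda = calendars["Turda"].entries
        t1974 = turda[turda.year == 1974].set_index("month")["severity"]
        assert t1974.to_dict() == {2: "severe", 3: "severe", 4: "extreme"}
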