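"""Schmidt number, gas transfer velocity, flux bounds and radon decay."""

import math

import numpy as np
import pytest

from sandch4.field_flux import (
    RadonSample,
    WindRecord,
    flux_bounds,
    gas_transfer_velocity,
    radon_decay_correct,
    schmidt_number,
    sea_air_flux,
)
from sandch4.gas_solubility import (
    AtmosphereSpec,
    SeawaterConditions,
    equilibrium_concentration,
)
from sandch4.units import RN222_HALF_LIFE_DAYS


class TestSchmidtNumber:
    def test_seawater_20C_matches_published_polynomial(self, temperate_seawater):
        """CH4 in seawater at 20 degC: the published third-order polynomial
        evaluates to 2039.2 - 120.31*20 + 3.4209*400 - 0.040437*8000 = 677.9."""
        assert schmidt_number(temperate_seawater) == pytest.approx(677.86, abs=0.1)

    def test_freshwater_20C_check_point(self):
        """Freshwater CH4 polynomial at 20 degC evaluates to 615.8."""
        cond = SeawaterConditions.from_celsius(20.0, 0.0)
        assert schmidt_number(cond) == pytest.approx(615.79, abs=0.1)

    def test_decreasing_in_temperature(self):
        for t in (0.0, 5.0, 10.0, 15.0, 20.0, 25.0):
            a = schmidt_number(SeawaterConditions.from_celsius(t, 35.0))
            b = schmidt_number(SeawaterConditions.from_celsius(t + 5.0, 35.0))
            assert a > b > 0

    def test_brackish_interpolates_between_polynomials(self):
        fresh = schmidt_number(SeawaterConditions.from_celsius(20.0, 0.0))
        brack = schmidt_number(SeawaterConditions.from_celsius(20.0, 17.5))
        sea = schmidt_number(SeawaterConditions.from_celsius(20.0, 35.0))
        assert brack == pytest.approx((fresh + sea) / 2.0, rel=1e-12)

    def test_out_of_fit_range_raises(self):
        with pytest.raises(ValueError, match="validity"):
            schmidt_number(SeawaterConditions.from_celsius(35.0, 35.0))


class TestGasTransferVelocity:
    def test_unity_schmidt_ratio(self):
        assert gas_transfer_velocity(4.0, 660.0) == pytest.approx(1.004)
        assert gas_transfer_velocity(0.0, 660.0) == 0.0

    def test_quadratic_mode(self):
        assert gas_transfer_velocity(4.0, 660.0, "quadratic") == pytest.approx(
            0.251 * 16.0
        )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            gas_transfer_velocity(4.0, 660.0, "cubic")

    def test_continuous_in_wind_speed(self):
        u = np.linspace(0.0, 15.0, 200)
        k = np.array([gas_transfer_velocity(x, 677.9) for x in u])
        assert (np.diff(k) >= 0).all()
        assert np.allclose(np.diff(k), np.diff(k)[0])  # linear in U10


class TestSeaAirFlux:
    def test_zero_at_equilibrium(
        self, ch4_bunsen, temperate_seawater, southern_atmosphere
    ):
        c_eq = equilibrium_concentration(
            temperate_seawater, southern_atmosphere, ch4_bunsen
        )
        est = sea_air_flux(
            c_eq, temperate_seawater, southern_atmosphere, 4.0, ch4_bunsen
        )
        assert est.flux_mg_m2_day == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_disequilibrium(
        self, ch4_bunsen, temperate_seawater, southern_atmosphere
    ):
        c_eq = equilibrium_concentration(
            temperate_seawater, southern_atmosphere, ch4_bunsen
        )
        f1 = sea_air_flux(
            c_eq + 10e-9, temperate_seawater, southern_atmosphere, 4.0, ch4_bunsen
        ).flux_mg_m2_day
        f2 = sea_air_flux(
            c_eq + 20e-9, temperate_seawater, southern_atmosphere, 4.0, ch4_bunsen
        ).flux_mg_m2_day
        assert f2 == pytest.approx(2.0 * f1, rel=1e-9)

    def test_hand_computed_synthetic_case(self, ch4_bunsen):
        """C=100 nM, C_eq approx 2.19 nM (1.8 ppm atmosphere), U10=4 m/s,
        20 degC, S=35. Hand chain: Sc=677.86 ->
        k = 0.251*4*(677.86/660)^-0.5 = 0.99069 cm/h = 0.23777 m/day;
        F = 0.23777 * (100-2.187)e-9 * 1000 * 16.04 * 1000 mg/m2/day = 0.3730."""
        cond = SeawaterConditions.from_celsius(20.0, 35.0)
        atm = AtmosphereSpec(1.8e-6)
        est = sea_air_flux(100e-9, cond, atm, 4.0, ch4_bunsen)
        assert est.flux_mg_m2_day == pytest.approx(0.373, rel=2e-3)

    def test_partial_pressure_form_agrees(self, ch4_bunsen, temperate_seawater,
                                          southern_atmosphere):
        """Both flux forms share K0 by construction, so they agree exactly."""
        a = sea_air_flux(50e-9, temperate_seawater, southern_atmosphere, 4.0,
                         ch4_bunsen, form="concentration")
        b = sea_air_flux(50e-9, temperate_seawater, southern_atmosphere, 4.0,
                         ch4_bunsen, form="partial-pressure")
        assert a.flux_mg_m2_day == pytest.approx(b.flux_mg_m2_day, rel=1e-12)

    def test_negative_concentration_rejected(
        self, ch4_bunsen, temperate_seawater, southern_atmosphere
    ):
        with pytest.raises(ValueError, match="non-negative"):
            sea_air_flux(-1e-9, temperate_seawater, southern_atmosphere, 4.0, ch4_bunsen)


class TestFluxBounds:
    def test_matches_brute_force_enumeration(
        self, ch4_bunsen, temperate_seawater, southern_atmosphere
    ):
        rng = np.random.default_rng(11)
        conc = rng.lognormal(np.log(50e-9), 1.0, size=40)
        wind = WindRecord(np.arange(730), rng.weibull(2.0, 730) * 6.0)
        bounds = flux_bounds(
            conc, temperate_seawater, southern_atmosphere, wind, ch4_bunsen
        )
        q1, q2, q3 = np.quantile(wind.u10, [0.25, 0.5, 0.75])
        expect = {
            "low": (conc.min(), q1),
            "mid": (conc.mean(), q2),
            "high": (conc.max(), q3),
        }
        for name, (c, u) in expect.items():
            ref = sea_air_flux(
                c, temperate_seawater, southern_atmosphere, float(u), ch4_bunsen
            )
            assert bounds[name].flux_mg_m2_day == ref.flux_mg_m2_day
        assert (
            bounds["low"].flux_mg_m2_day
            <= bounds["mid"].flux_mg_m2_day
            <= bounds["high"].flux_mg_m2_day
        )

    def test_degenerate_survey_collapses(self, ch4_bunsen, temperate_seawater,
                                         southern_atmosphere):
        wind = WindRecord(np.arange(4), np.full(4, 5.0))
        bounds = flux_bounds([80e-9] * 5, temperate_seawater, southern_atmosphere,
                             wind, ch4_bunsen)
        vals = [b.flux_mg_m2_day for b in bounds.values()]
        assert vals[0] == vals[1] == vals[2]

    def test_all_equilibrium_survey_gives_zero_everywhere(
        self, ch4_bunsen, temperate_seawater, southern_atmosphere
    ):
        c_eq = equilibrium_concentration(
            temperate_seawater, southern_atmosphere, ch4_bunsen
        )
        wind = WindRecord(np.arange(10), np.linspace(1, 10, 10))
        bounds = flux_bounds([c_eq] * 8, temperate_seawater, southern_atmosphere,
                             wind, ch4_bunsen)
        for est in bounds.values():
            assert est.flux_mg_m2_day == pytest.approx(0.0, abs=1e-12)

    def test_empty_inputs_rejected(self, ch4_bunsen, temperate_seawater,
                                   southern_atmosphere):
        with pytest.raises(ValueError, match="empty"):
            WindRecord(np.array([]), np.array([]))
        wind = WindRecord(np.arange(2), np.array([3.0, 4.0]))
        with pytest.raises(ValueError, match="empty"):
            flux_bounds([], temperate_seawater, southern_atmosphere, wind, ch4_bunsen)


class TestRadon:
    def test_no_elapsed_time_is_identity(self):
        assert radon_decay_correct(RadonSample(100.0, 0.0)) == 100.0

    def test_one_half_life_doubles(self):
        assert radon_decay_correct(
            RadonSample(100.0, RN222_HALF_LIFE_DAYS)
        ) == pytest.approx(200.0, rel=1e-12)

    def test_one_day_correction(self):
        """100 Bq/m3 measured a day late: 100*exp(ln2/3.8235) = 119.87."""
        expected = 100.0 * math.exp(math.log(2.0) / 3.8235)
        assert radon_decay_correct(RadonSample(100.0, 1.0)) == pytest.approx(expected)

    def test_negative_elapsed_time_rejected(self):
        with pytest.raises(ValueError):
            radon_decay_correct(RadonSample(100.0, -1.0))
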