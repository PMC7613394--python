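import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uavtraits.trait_core import (
    FixedCanopyParams,
    MiniRTMConstants,
    SensorModel,
    Spectrum,
    TraitSample,
    _mini_rtm_components,
    add_noise,
    ccc_from,
    default_grid,
    fcover_from,
    lcc_to_spad,
    resample_to_sensor,
    simulate_canopy,
    simulate_canopy_batch,
    spad_to_lcc,
)


class TestTraitFormulas:
    @pytest.mark.parametrize("spad,expected,tol", [
        (0.0, 0.0913, 1e-12),      # e^0 = 1
        (50.0, 0.7272, 1e-4),
    ])
    def test_spad_conversion_values(self, spad, expected, tol):
        assert spad_to_lcc(spad) == pytest.approx(expected, abs=tol)

    def test_spad_conversion_monotone(self):
        assert spad_to_lcc(60) > spad_to_lcc(50)

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_spad_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            spad_to_lcc(bad)

    def test_spad_roundtrip(self):
        assert lcc_to_spad(spad_to_lcc(42.0)) == pytest.approx(42.0, abs=1e-10)

    @pytest.mark.parametrize("cv,lai,expected,tol", [
        (0.9, 0.0, 0.0, 1e-12),          # gap fraction 1 at LAI 0
        (0.71, 2.85, 0.5619, 1e-4),
        (1.0, 1000.0, 1.0, 1e-12),       # asymptote to Cv
    ])
    def test_fcover_values(self, cv, lai, expected, tol):
        assert fcover_from(cv, lai, 0.55) == pytest.approx(expected, abs=tol)

    def test_fcover_rejects_bad_cv(self):
        with pytest.raises(ValueError):
            fcover_from(1.2, 1.0)

    @pytest.mark.parametrize("lai,lcc,expected,tol", [
        (0.0, 65.0, 0.0, 1e-12),
        (2.85, 65.36, 1.8628, 1e-4),
        (2.04, 70.588, 1.44, 1e-3),
    ])
    def test_ccc_values(self, lai, lcc, expected, tol):
        assert ccc_from(lai, lcc) == pytest.approx(expected, abs=tol)

    def test_ccc_rejects_negative(self):
        with pytest.raises(ValueError):
            ccc_from(-1.0, 50.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        spad=st.floats(0, 100),
        cv=st.floats(0, 1),
        lai=st.floats(0, 8),
        lcc=st.floats(0, 120),
    )
    def test_formulas_match_scalar_math_oracle(self, spad, cv, lai, lcc):
        """Vectorised formulas agree with direct scalar evaluation."""
        assert spad_to_lcc(spad) == pytest.approx(
            0.0913 * math.exp(0.0415 * spad), rel=1e-10)
        assert fcover_from(cv, lai) == pytest.approx(
            cv * (1 - math.exp(-0.55 * lai)), rel=1e-10, abs=1e-300)
        assert ccc_from(lai, lcc) == pytest.approx(
            0.01 * lai * lcc, rel=1e-10, abs=1e-300)


class TestSensorModel:
    def test_band_layout(self, sensor):
        assert len(sensor) == 40
        assert np.all(np.diff(sensor.centers) >= 0)
        assert sensor.fwhm.min() >= 15 and sensor.fwhm.max() <= 27
        # the shared camera boundary appears twice
        assert np.sum(sensor.centers == 638.0) == 2

    def test_band_labels_unique(self, sensor):
        assert len(set(sensor.band_labels)) == 40

    def test_serialization_roundtrip(self, sensor):
        back = SensorModel.from_dict(sensor.to_dict())
        np.testing.assert_allclose(back.centers, sensor.centers)
        np.testing.assert_allclose(back.fwhm, sensor.fwhm)


class TestMiniRTM:
    def test_no_vegetation_returns_soil(self):
        grid = default_grid()
        fixed = FixedCanopyParams()
        spec = simulate_canopy(TraitSample(lai=0, lcc=55, cv=0.5), fixed, grid)
        soil, _ = _mini_rtm_components(grid, 55.0, fixed.n_struct, fixed.sm,
                                       MiniRTMConstants())
        np.testing.assert_allclose(spec.reflectance, soil, atol=1e-14)

    def test_dense_canopy_limit_at_850(self):
        grid = default_grid()
        fixed = FixedCanopyParams()
        c = MiniRTMConstants()
        traits = TraitSample(lai=7, lcc=60, cv=1.0)
        spec = simulate_canopy(traits, fixed, grid)
        soil, dense = _mini_rtm_components(np.array([850.0]), 60.0,
                                           fixed.n_struct, fixed.sm, c)
        i = int(np.where(grid == 850.0)[0][0])
        # fCover -> 1 within 1e-2 at LAI 7, and the reflectance matches
        # the closed-form mixture exactly
        fc = fcover_from(1.0, 7.0)
        assert 1.0 - fc < 0.03
        exact = fc * dense[0] + (1 - fc) * soil[0]
        assert abs(spec.reflectance[i] - exact) < 1e-6

    def test_chlorophyll_darkens_red(self):
        grid = default_grid()
        fixed = FixedCanopyParams()
        i = int(np.where(grid == 672.0)[0][0])
        lo = simulate_canopy(TraitSample(3, 40, 0.9), fixed, grid)
        hi = simulate_canopy(TraitSample(3, 90, 0.9), fixed, grid)
        assert hi.reflectance[i] < lo.reflectance[i]

    def test_lai_brightens_nir(self):
        grid = default_grid()
        fixed = FixedCanopyParams()
        i = int(np.where(grid == 850.0)[0][0])
        r = [simulate_canopy(TraitSample(lai, 60, 0.8), fixed, grid)
             .reflectance[i] for lai in (0.5, 2.0, 5.0)]
        assert r[0] < r[1] < r[2]

    def test_reflectance_bounded(self):
        grid = default_grid()
        R = simulate_canopy_batch(
            np.array([0.05, 3, 7]), np.array([40, 65, 90]),
            np.array([0.05, 0.7, 1.0]), np.array([1.0, 1.7, 2.5]),
            FixedCanopyParams(), grid,
        )
        assert np.all(R > 0) and np.all(R < 1)

    def test_rejects_out_of_range_grid(self):
        with pytest.raises(ValueError):
            simulate_canopy(TraitSample(1, 50, 0.5), FixedCanopyParams(),
                            np.array([300.0, 500.0]))

    def test_batch_matches_single(self):
        grid = default_grid()
        fixed = FixedCanopyParams()
        single = simulate_canopy(
            TraitSample(2.5, 55, 0.6, n_struct=1.8), fixed, grid)
        batch = simulate_canopy_batch(
            np.array([2.5]), np.array([55.0]), np.array([0.6]),
            np.array([1.8]), fixed, grid)
        np.testing.assert_allclose(batch[0], single.reflectance, atol=1e-14)

    @settings(derandomize=True, max_examples=100)
    @given(cv=st.floats(0.01, 1), lai=st.floats(0, 7))
    def test_mixing_identity(self, cv, lai):
        """Crown-cover mixing of within-crown interception equals the
        fCover-weighted soil/vegetation mixture."""
        grid = np.linspace(450, 950, 21)
        fixed = FixedCanopyParams()
        soil, dense = _mini_rtm_components(grid, 60.0, fixed.n_struct,
                                           fixed.sm, MiniRTMConstants())
        beta = 1 - np.exp(-0.55 * lai)
        lhs_mix = cv * (beta * dense + (1 - beta) * soil) + (1 - cv) * soil
        fc = fcover_from(cv, lai)
        rhs_mix = fc * dense + (1 - fc) * soil
        np.testing.assert_allclose(lhs_mix, rhs_mix, atol=1e-12)


class TestResampling:
    def test_constant_preserved(self, sensor):
        grid = default_grid()
        out = resample_to_sensor(Spectrum(grid, np.full(grid.size, 0.3)),
                                 sensor)
        np.testing.assert_allclose(out.reflectance, 0.3, atol=1e-10)
        assert len(out.reflectance) == 40

    def test_linear_input_maps_to_band_centers(self, sensor):
        grid = default_grid()
        a, b = 0.01, 1e-4
        out = resample_to_sensor(Spectrum(grid, a + b * grid), sensor)
        np.testing.assert_allclose(out.reflectance, a + b * sensor.centers,
                                   atol=1e-6)

    def test_insufficient_coverage_names_band(self, sensor):
        grid = np.arange(500.0, 1000.0)
        with pytest.raises(ValueError, match="band 0"):
            resample_to_sensor(Spectrum(grid, np.full(grid.size, 0.2)),
                               sensor)

    @settings(derandomize=True, max_examples=50)
    @given(value=st.floats(0.0, 1.0))
    def test_normalization_conserves_any_constant(self, value, sensor):
        grid = default_grid()
        out = resample_to_sensor(Spectrum(grid, np.full(grid.size, value)),
                                 sensor)
        np.testing.assert_allclose(out.reflectance, value, atol=1e-10)


class TestNoise:
    def test_zero_sigma_identity(self, sensor):
        spec = Spectrum(sensor.centers, np.full(40, 0.4))
        out = add_noise(spec, sigma=0.0, rng=0)
        np.testing.assert_array_equal(out.reflectance, spec.reflectance)

    def test_noise_sd_in_chi2_band(self):
        lam = np.arange(10000, dtype=float)
        spec = Spectrum(lam, np.full(10000, 0.5))  # far from clipping
        out = add_noise(spec, sigma=0.005, rng=3)
        sd = np.std(out.reflectance - spec.reflectance, ddof=1)
        assert 0.0045 < sd < 0.0055

    def test_seeded_determinism(self):
        spec = Spectrum(np.arange(40.0), np.full(40, 0.4))
        a = add_noise(spec, rng=9)
        b = add_noise(spec, rng=9)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_multiplicative_mode_scales(self):
        spec = Spectrum(np.arange(1000.0), np.full(1000, 0.5))
        out = add_noise(spec, sigma=0.01, mode="multiplicative", rng=4)
        sd = np.std(out.reflectance / spec.reflectance - 1.0, ddof=1)
        assert 0.008 < sd < 0.012
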