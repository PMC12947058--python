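"""Compound-Poisson engine: geometry, calibration, moments, sampling."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import filmdose as fd
from filmdose.engine import DeltaEvent, EmpiricalEvent, GammaEvent, LognormalEvent
from filmdose.errors import CalibrationError, DomainError, InvalidGeometryError


class TestGeometry:
    def test_cube_mean_chord_is_two_thirds_side(self):
        assert fd.mean_chord_length(fd.VoxelGeometry(3.0, 3.0, 3.0)) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "preset,expected",
        [("vx-sm", 0.825255), ("vx-lg", 1.334098)],  # 4V/S, frozen from the formula
    )
    def test_preset_mean_chords(self, preset, expected):
        geom = fd.VoxelGeometry.from_preset(preset)
        assert geom.mean_chord == pytest.approx(expected, rel=1e-5)

    def test_preset_dimensions(self):
        assert (fd.VX_SM.dx, fd.VX_SM.dz) == (0.8862, 6.0)
        assert (fd.VX_LG.dx, fd.VX_LG.dz) == (1.436, 9.4)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            fd.VoxelGeometry(1.0, -1.0, 1.0)
        with pytest.raises(InvalidGeometryError):
            fd.VoxelGeometry(1.0, 1.0, 1.0, density=0.0)


class TestCalibration:
    def test_anchor_identification(self, vxsm_model):
        # lambda = -ln 0.65, mu1 = D/lambda, m2/mu1^2 = spread^2 * lambda
        assert vxsm_model.mu1 == pytest.approx(6.964e-3, rel=1e-3)
        assert vxsm_model.m2 / vxsm_model.mu1**2 == pytest.approx(5.068, rel=1e-3)

    def test_large_voxel_anchor(self, vxlg_model):
        lam = 0.003 / vxlg_model.mu1
        assert lam == pytest.approx(1.0498, rel=1e-3)
        assert vxlg_model.mu1 == pytest.approx(2.858e-3, rel=1e-3)

    def test_unit_spread_anchor_degenerates_to_delta(self):
        model = fd.calibrate_from_anchor(
            fd.CalibrationAnchor(0.01, math.exp(-1), 1.0)
        )
        assert isinstance(model, DeltaEvent)
        assert model.mu1 == pytest.approx(0.01)
        assert model.m2 == pytest.approx(1e-4)

    def test_round_trip_reproduces_anchor(self, vxsm_model, vxlg_model):
        for model, (fz0, spread) in [(vxsm_model, (0.65, 3.43)), (vxlg_model, (0.35, 2.05))]:
            assert fd.zero_fraction(model, 0.003) == pytest.approx(fz0, rel=1e-12)
            assert fd.analytic_spread(model, 0.003) == pytest.approx(spread, rel=1e-12)

    def test_zero_zero_fraction_unidentifiable(self):
        with pytest.raises(CalibrationError):
            fd.calibrate_from_anchor(fd.CalibrationAnchor(0.003, 0.0, 1.0))

    def test_lognormal_family_matches_moments(self):
        model = fd.calibrate_from_anchor(
            fd.CalibrationAnchor(0.003, 0.65, 3.43), family="lognormal"
        )
        assert model.mu1 == pytest.approx(6.964e-3, rel=1e-3)
        assert model.m2 / model.mu1**2 == pytest.approx(5.068, rel=1e-3)


class TestEventFrequency:
    def test_one_event_when_dose_equals_mu1(self):
        assert fd.event_frequency(DeltaEvent(0.003), 0.003) == pytest.approx(1.0)

    def test_scales_linearly_with_dose(self, vxsm_model):
        # anchor lambda = -ln 0.65 at 0.003 Gy, so 10x dose -> 4.308
        assert fd.event_frequency(vxsm_model, 0.03) == pytest.approx(4.308, rel=1e-3)

    def test_zero_dose_zero_events(self, vxsm_model):
        assert fd.event_frequency(vxsm_model, 0.0) == 0.0

    def test_negative_dose_rejected(self, vxsm_model):
        with pytest.raises(DomainError):
            fd.event_frequency(vxsm_model, -0.1)


class TestAnalyticSpread:
    def test_table_value_at_10x_anchor_dose(self, vxsm_model):
        # inverse-square-root scaling: 3.43 * sqrt(1/10) = 1.085 (printed 108%)
        assert fd.analytic_spread(vxsm_model, 0.03) == pytest.approx(1.085, rel=1e-3)

    def test_inverse_square_root_dose_scaling(self, vxsm_model):
        assert fd.analytic_spread(vxsm_model, 0.01) / fd.analytic_spread(
            vxsm_model, 0.04
        ) == pytest.approx(2.0, rel=1e-12)

    def test_delta_model_is_poissonian(self):
        model = DeltaEvent(0.001)
        assert fd.analytic_spread(model, 0.1) == pytest.approx(0.1)  # sqrt(1/lambda), lambda=100

    def test_nonpositive_dose_rejected(self, vxsm_model):
        with pytest.raises(DomainError):
            fd.analytic_spread(vxsm_model, 0.0)

    @given(dose=st.floats(1e-4, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_spread_times_sqrt_dose_constant(self, dose):
        model = GammaEvent(0.25, 0.03)
        ref = fd.analytic_spread(model, 0.003) * math.sqrt(0.003)
        assert fd.analytic_spread(model, dose) * math.sqrt(dose) == pytest.approx(ref, rel=1e-9)

    def test_fixed_event_energy_spread_scales_with_inverse_sqrt_volume(self):
        # one event = fixed energy E in the voxel mass: z0 = E / mass ~ 1/V
        e_joule = 1e-15
        spreads = {}
        for name in ("vx-sm", "vx-lg"):
            geom = fd.VoxelGeometry.from_preset(name)
            model = DeltaEvent(e_joule / geom.mass_kg)
            spreads[name] = fd.analytic_spread(model, 0.01)
        expected = math.sqrt(fd.VX_LG.volume / fd.VX_SM.volume)
        assert spreads["vx-sm"] / spreads["vx-lg"] == pytest.approx(expected, rel=1e-9)


class TestZeroFraction:
    def test_unity_at_zero_dose(self, vxsm_model):
        assert fd.zero_fraction(vxsm_model, 0.0) == 1.0

    def test_single_event_mean(self):
        assert fd.zero_fraction(DeltaEvent(0.01), 0.01) == pytest.approx(math.exp(-1))

    def test_strictly_decreasing_in_dose(self, vxsm_model):
        doses = np.linspace(0.001, 0.5, 20)
        vals = [fd.zero_fraction(vxsm_model, d) for d in doses]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestLaplaceTransforms:
    @pytest.mark.parametrize(
        "model",
        [
            DeltaEvent(0.005),
            GammaEvent(0.25, 0.028),
            LognormalEvent(-5.8, 1.2),
            EmpiricalEvent((0.001, 0.004, 0.02), (0.5, 0.3, 0.2)),
        ],
        ids=["delta", "gamma", "lognormal", "empirical"],
    )
    def test_unity_at_zero_and_strictly_decreasing(self, model):
        assert model.laplace(0.0) == pytest.approx(1.0, abs=1e-9)
        alphas = np.geomspace(0.01, 1e4, 12)
        vals = np.array([float(model.laplace(a)) for a in alphas])
        assert (np.diff(vals) < 0).all()
        assert (vals >= 0).all()

    def test_lognormal_quadrature_against_monte_carlo(self):
        model = LognormalEvent(-5.8, 1.2)
        rng = np.random.default_rng(5)
        draws = model.sample(400_000, rng)
        for alpha in (1.0, 50.0):
            mc = np.exp(-alpha * draws)
            se = mc.std() / math.sqrt(mc.size)
            assert model.laplace(alpha) == pytest.approx(mc.mean(), abs=4 * se)

    def test_moment_matching_round_trip(self):
        for cls in (GammaEvent, LognormalEvent):
            model = cls.from_moments(6.964e-3, 5.068 * 6.964e-3**2)
            assert model.mu1 == pytest.approx(6.964e-3, rel=1e-9)
            assert model.m2 == pytest.approx(5.068 * 6.964e-3**2, rel=1e-9)


class TestSampling:
    def test_zero_dose_gives_all_zero_field(self, vxsm_model):
        field = fd.sample_field(vxsm_model, fd.VX_SM, 0.0, (10, 10, 2), seed=0)
        assert (field.values == 0).all()

    def test_zero_fraction_matches_poisson_identity(self, anchor_field_1e6):
        frac = (anchor_field_1e6.values == 0).mean()
        se = math.sqrt(0.65 * 0.35 / anchor_field_1e6.values.size)
        assert abs(frac - 0.65) < 3 * se

    def test_delta_field_mean(self):
        model = DeltaEvent(0.01)
        field = fd.sample_field(model, fd.VX_SM, 0.02, (100, 100, 100), seed=7)
        z = field.values.ravel()
        se = z.std() / math.sqrt(z.size)
        assert abs(z.mean() - 0.02) < 3 * se

    def test_sampled_spread_matches_analytic(self, vxsm_model, anchor_field_1e6):
        s = fd.summarize_field(anchor_field_1e6)
        assert s.spread == pytest.approx(fd.analytic_spread(vxsm_model, 0.003), rel=0.05)

    def test_reproducible_for_fixed_seed(self, vxsm_model):
        a = fd.sample_field(vxsm_model, fd.VX_SM, 0.01, (50, 50, 2), seed=42)
        b = fd.sample_field(vxsm_model, fd.VX_SM, 0.01, (50, 50, 2), seed=42)
        assert (a.values == b.values).all()

    def test_scaled_model_aggregates_variance(self, vxsm_model):
        # mean of n voxels = compound Poisson with event size / n: spread / sqrt(n)
        n = 100
        scaled = vxsm_model.scaled(1.0 / n)
        assert fd.analytic_spread(scaled, 0.01) == pytest.approx(
            fd.analytic_spread(vxsm_model, 0.01) / math.sqrt(n), rel=1e-9
        )


class TestSurvivalTransform:
    def test_unity_at_alpha_zero(self, vxsm_model):
        assert fd.survival_transform(vxsm_model, 0.01, 0.0) == pytest.approx(1.0)

    def test_limit_is_zero_fraction(self, vxsm_model):
        # gamma spectra carry mass near z = 0, so the limit is approached
        # as a power law in alpha rather than exponentially
        assert fd.survival_transform(vxsm_model, 0.003, 1e15) == pytest.approx(
            fd.zero_fraction(vxsm_model, 0.003), rel=1e-3
        )
        assert fd.survival_transform(DeltaEvent(0.005), 0.003, 1e4) == pytest.approx(
            fd.zero_fraction(DeltaEvent(0.005), 0.003), rel=1e-9
        )

    def test_delta_closed_form_against_monte_carlo(self):
        model, dose, alpha = DeltaEvent(0.01), 0.02, 30.0
        field = fd.sample_field(model, fd.VX_SM, dose, (100, 100, 100), seed=11)
        mc = np.exp(-alpha * field.values.ravel())
        se = mc.std() / math.sqrt(mc.size)
        assert fd.survival_transform(model, dose, alpha) == pytest.approx(
            mc.mean(), abs=3 * se
        )

    def test_matches_histogram_integration(self, vxsm_model, anchor_field_1e6):
        hist = fd.histogram_f(anchor_field_1e6, n_bins=400)
        for alpha in (0.1, 1.0, 10.0):
            closed = fd.survival_transform(vxsm_model, 0.003, alpha)
            assert fd.response_integral(hist, alpha) == pytest.approx(closed, rel=5e-3)
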