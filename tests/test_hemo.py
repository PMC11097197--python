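"""Hemodynamic parameters: flow integrals, DUS-style reconstruction,
vector complexity, TAWSS, Reynolds number and Kolmogorov length."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoveloc import (
    flow_rate_from_centerline,
    flow_rate_from_profile,
    kolmogorov_length,
    poiseuille_profile,
    profile_to_field,
    reynolds_number,
    sample_centerline,
    tawss,
    tube_walls,
    vector_complexity,
    womersley_profile,
)
from hemoveloc.types import FlowProfile, VelocityField2D


def small_field(vx, vy, n=8):
    vx = np.broadcast_to(np.asarray(vx, float), (1, n, n)).copy()
    vy = np.broadcast_to(np.asarray(vy, float), (1, n, n)).copy()
    return VelocityField2D(
        x=np.arange(float(n)), y=np.arange(float(n)), t=np.array([0.0]),
        vx=vx, vy=vy, mask=np.ones((n, n), dtype=bool),
    )


class TestFlowRateFromProfile:
    def test_parabolic_closed_form(self):
        """Q = pi u_max R^2 / 2 for a parabola, to 0.1% at 200 samples."""
        r = np.linspace(-1.0, 1.0, 201)
        u = (1.0 - r**2)[None, :]  # u_max = 1 cm/s, R = 1 mm
        prof = FlowProfile(r=r, time=np.array([0.0]), u=u, radius=1.0)
        q = flow_rate_from_profile(prof).flow_rate[0]
        expect = np.pi * (1.0 * 10.0) * 1.0**2 / 2.0 * 1e-3  # mL/s
        assert q == pytest.approx(expect, rel=1e-3)

    def test_uniform_closed_form(self):
        """Q = pi c R^2 for a top-hat profile."""
        r = np.linspace(-1.0, 1.0, 201)
        u = np.ones((1, 201))
        prof = FlowProfile(r=r, time=np.array([0.0]), u=u, radius=1.0)
        q = flow_rate_from_profile(prof).flow_rate[0]
        assert q == pytest.approx(np.pi * 10.0 * 1e-3, rel=1e-3)

    def test_zero_profile(self):
        r = np.linspace(-1.0, 1.0, 51)
        prof = FlowProfile(r=r, time=np.array([0.0]), u=np.zeros((1, 51)),
                           radius=1.0)
        assert flow_rate_from_profile(prof).flow_rate[0] == 0.0

    def test_wall_extrapolation_warns(self):
        r = np.linspace(-0.8, 0.8, 41)
        u = np.ones((1, 41))
        prof = FlowProfile(r=r, time=np.array([0.0]), u=u, radius=1.0)
        with pytest.warns(UserWarning, match="extrapolating"):
            flow_rate_from_profile(prof)


class TestFlowRateFromCenterline:
    def test_steady_centerline_inverts_poiseuille(self, fluid):
        """32.1 cm/s centerline in an 8.9 mm tube -> ~10 mL/s."""
        v = np.full(100, 32.148454607629404)
        wf = flow_rate_from_centerline(v, 4.45, fluid)
        np.testing.assert_allclose(wf.flow_rate, 10.0, rtol=1e-6)

    def test_womersley_round_trip(self, waveform, fluid):
        """Forward profile -> centerline -> reconstruction recovers the
        waveform to < 1% RMS at 20 harmonics."""
        prof = womersley_profile(waveform, 4.45, fluid, n_harmonics=20)
        center = sample_centerline(prof)
        wf_back = flow_rate_from_centerline(center, 4.45, fluid,
                                            n_harmonics=20,
                                            period=waveform.period)
        rms = np.sqrt(np.mean((wf_back.flow_rate - waveform.flow_rate) ** 2))
        scale = np.sqrt(np.mean(waveform.flow_rate**2))
        assert rms / scale < 0.01

    def test_dus_bias_scales_reconstruction(self, waveform, fluid):
        prof = womersley_profile(waveform, 4.45, fluid)
        biased = sample_centerline(prof, bias=1.3)
        wf_b = flow_rate_from_centerline(biased, 4.45, fluid,
                                         period=waveform.period)
        wf_0 = flow_rate_from_centerline(sample_centerline(prof), 4.45, fluid,
                                         period=waveform.period)
        np.testing.assert_allclose(wf_b.flow_rate, 1.3 * wf_0.flow_rate,
                                   rtol=1e-9, atol=1e-9)

    def test_zero_series(self, fluid):
        wf = flow_rate_from_centerline(np.zeros(50), 4.45, fluid)
        np.testing.assert_allclose(wf.flow_rate, 0.0, atol=1e-12)

    def test_radius_error(self, fluid):
        with pytest.raises(ValueError):
            flow_rate_from_centerline(np.ones(10), -1.0, fluid)


class TestVectorComplexity:
    def test_unidirectional_flow_zero(self):
        res = vector_complexity(small_field(1.0, 0.0))
        assert res.vc[0] == 0.0

    def test_opposite_directions_unity(self):
        vx = np.ones((1, 8, 8))
        vx[:, :, 4:] = -1.0
        res = vector_complexity(small_field(vx[0], 0.0))
        assert res.vc[0] == pytest.approx(1.0)

    def test_half_x_half_y(self):
        """Half +x, half +y gives VC = 1 - sqrt(1/2)."""
        vx = np.ones((8, 8))
        vy = np.zeros((8, 8))
        vx[:, 4:] = 0.0
        vy[:, 4:] = 1.0
        res = vector_complexity(small_field(vx, vy))
        assert res.vc[0] == pytest.approx(1.0 - np.sqrt(0.5), rel=1e-12)

    def test_all_zero_vectors_reported_missing(self):
        res = vector_complexity(small_field(0.0, 0.0))
        assert np.isnan(res.vc[0])
        assert res.n_vectors[0] == 0

    def test_empty_region_rejected(self):
        f = small_field(1.0, 0.0)
        with pytest.raises(ValueError):
            vector_complexity(f, region=np.zeros((8, 8), dtype=bool))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        angle=st.floats(min_value=-np.pi, max_value=np.pi),
        scale=st.floats(min_value=0.01, max_value=100.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_bounds_scale_and_rotation_invariance(self, angle, scale, seed):
        """VC lies in [0,1] and is invariant under uniform magnitude
        scaling and global rotation of all vectors."""
        rng = np.random.default_rng(seed)
        vx = rng.normal(size=(8, 8))
        vy = rng.normal(size=(8, 8))
        base = vector_complexity(small_field(vx, vy)).vc[0]
        assert 0.0 <= base <= 1.0
        scaled = vector_complexity(small_field(scale * vx, scale * vy)).vc[0]
        assert scaled == pytest.approx(base, abs=1e-9)
        ca, sa = np.cos(angle), np.sin(angle)
        rot = vector_complexity(
            small_field(ca * vx - sa * vy, sa * vx + ca * vy)).vc[0]
        assert rot == pytest.approx(base, abs=1e-9)


class TestTawss:
    @pytest.fixture(scope="class")
    def poiseuille_field(self):
        R, u_max = 4.45, 100.0
        q = (u_max / 100) * np.pi * (R * 1e-3) ** 2 / 2 * 1e6
        prof = poiseuille_profile(q, R, n_radial=201)
        return profile_to_field(prof, length=20.0, grid_spacing=0.4), R, u_max

    def test_steady_poiseuille_matches_closed_form(self, poiseuille_field,
                                                   fluid):
        """TAWSS = 2 mu u_max / R (~1.87 Pa) within 10% on both walls."""
        field, R, u_max = poiseuille_field
        expect = 2 * fluid.dynamic_viscosity * (u_max / 100) / (R * 1e-3)
        for wall in tube_walls(field):
            prof = tawss(field, wall, fluid)
            good = np.isfinite(prof.tawss)
            assert good.sum() >= prof.tawss.size // 2
            np.testing.assert_allclose(prof.tawss[good], expect, rtol=0.10)

    def test_zero_flow_zero_tawss(self, fluid):
        f = small_field(0.0, 0.0, n=16)
        f.attrs["radius_mm"] = 7.0
        upper, _ = tube_walls(f)
        prof = tawss(f, upper, fluid, sample_depth=4.0)
        good = np.isfinite(prof.tawss)
        np.testing.assert_allclose(prof.tawss[good], 0.0, atol=1e-12)

    def test_linearity_in_velocity(self, poiseuille_field, fluid):
        field, _, _ = poiseuille_field
        doubled = VelocityField2D(x=field.x, y=field.y, t=field.t,
                                  vx=2 * field.vx, vy=2 * field.vy,
                                  mask=field.mask, attrs=field.attrs)
        upper, _ = tube_walls(field)
        a = tawss(field, upper, fluid).tawss
        b = tawss(doubled, upper, fluid).tawss
        good = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(b[good], 2 * a[good], rtol=1e-9)

    def test_parameter_validation(self, poiseuille_field, fluid):
        field, _, _ = poiseuille_field
        upper, _ = tube_walls(field)
        with pytest.raises(ValueError):
            tawss(field, upper, fluid, sample_depth=0.1)
        with pytest.raises(ValueError):
            tawss(field, upper, fluid, n_samples=3)


class TestTurbulenceScales:
    def test_transitional_femoral_reynolds(self):
        """v = 1550 mm/s, L = 8.9 mm, rho = 1.14e-6 kg/mm^3,
        mu = 4.16e-6 kg/(mm s) -> Re = 3780."""
        re = reynolds_number(1550.0, 8.9, 1.14e-6, 4.16e-6)
        assert round(re) == 3780

    def test_linearity_in_velocity(self):
        a = reynolds_number(1000.0, 8.9, 1.14e-6, 4.16e-6)
        b = reynolds_number(2000.0, 8.9, 1.14e-6, 4.16e-6)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_dimensional_invariance(self):
        """Consistent unit rescaling (mm -> m) leaves Re unchanged."""
        re_mm = reynolds_number(1550.0, 8.9, 1.14e-6, 4.16e-6)
        re_si = reynolds_number(1.550, 8.9e-3, 1.14e-6 * 1e9, 4.16e-6 * 1e3)
        assert re_si == pytest.approx(re_mm, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            reynolds_number(0.0, 8.9, 1.14e-6, 4.16e-6)

    def test_kolmogorov_formula_value(self):
        """l_c Re^(-3/4) with Re = 3780, l_c = 8.9 mm is ~0.0185 mm."""
        eta = kolmogorov_length(3780.0, 8.9)
        assert eta == pytest.approx(8.9 * 3780.0 ** (-0.75), rel=1e-12)
        assert eta == pytest.approx(0.0185, abs=0.0005)

    def test_unit_reynolds_identity(self):
        assert kolmogorov_length(1.0, 5.5) == 5.5

    def test_monotone_decreasing_in_re(self):
        etas = [kolmogorov_length(re, 8.9) for re in (100, 1000, 10000)]
        assert etas[0] > etas[1] > etas[2]
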