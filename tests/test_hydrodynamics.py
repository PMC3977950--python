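"""Hydrodynamic metric suite on analytic, synthetic and solver fields."""

import math

import numpy as np
import pytest

from csfhydro.fieldio import VelocityField
from csfhydro.hydrodynamics import (
    BIDIRECTIONAL_THRESHOLD,
    ExternalFlowSpec,
    MetricError,
    bidirectional_velocity,
    one_sided_wall_gradient,
    peak_velocities,
    pressure_gradient_stats,
    reynolds_external,
    reynolds_internal,
    secondary_flow_parameter,
    vortex_frequency,
    wall_shear_from_samples,
    wall_shear_stress_annulus,
    wall_shear_stress_solution,
)
from csfhydro.synthetic import SyntheticFieldSpec, make_flow_waveform, make_synthetic_field


def _plane_field(axial_by_time, weights=None, period=1.0):
    """Helper: build a planar field from (K, N) axial samples (cm/s)."""
    K, N = axial_by_time.shape
    pts = np.column_stack([np.arange(N, dtype=float),
                           np.zeros(N), np.zeros(N)])
    vel = np.zeros((K, N, 3))
    vel[:, :, 1] = axial_by_time
    w = np.ones(N) if weights is None else weights
    times = np.arange(K) * period / K
    return VelocityField(points=pts, times=times, velocity=vel,
                         weights=w, period=period)


class TestPeakVelocities:
    def test_zero_field(self):
        fld = _plane_field(np.zeros((10, 5)))
        v_sys, v_dia = peak_velocities(fld)
        assert (v_sys, v_dia) == (0.0, 0.0)

    def test_synthetic_jet_amplitude_recovered(self):
        spec = SyntheticFieldSpec(axial_amplitude=4.5, n_steps=100)
        fld, gt = make_synthetic_field(spec)
        v_sys, v_dia = peak_velocities(fld)
        assert v_sys == pytest.approx(gt.v_sys, rel=1e-9)
        assert v_sys == pytest.approx(4.5, rel=1e-3)

    def test_poiseuille_centerline_is_twice_mean(
            self, pipe_section, pipe_mesh, fluid):
        from csfhydro.solver import solve_waveform
        wf = make_flow_waveform(period=1000.0, stroke_volume=None,
                                harmonics=[(1, 1.0, 0.0)], n_samples=64)
        sol = solve_waveform(pipe_section, fluid, wf, mesh=pipe_mesh)
        fld = sol.time_domain(n_steps=64)
        v_sys, _ = peak_velocities(fld, waveform=wf)
        u_mean = 1.0 / pipe_section.area * 100  # (mL/s)/mm^2 -> cm/s
        assert v_sys == pytest.approx(2 * u_mean, rel=5e-3)

    def test_plane_outside_domain_rejected(self):
        fld = _plane_field(np.zeros((4, 5)))
        with pytest.raises(MetricError):
            peak_velocities(fld, y=99.0)


class TestBidirectional:
    def test_unidirectional_plug_is_zero(self):
        fld = _plane_field(np.ones((20, 8)))
        assert bidirectional_velocity(fld) == (0.0, 0.0)

    def test_constructed_split_flow(self):
        # +2 cm/s on one half, -1 cm/s on the other, for 3 of 10 steps
        axial = np.zeros((10, 10))
        axial[2:5, :5] = 2.0
        axial[2:5, 5:] = -1.0
        fld = _plane_field(axial, period=1.0)
        v_bi, dur = bidirectional_velocity(fld)
        assert v_bi == 3.0
        assert dur == pytest.approx(0.3)

    def test_threshold_gates_duration(self):
        axial = np.zeros((10, 4))
        axial[:, 0] = 0.04     # +0.4 mm/s
        axial[:, 1] = -0.04    # B = 0.8 mm/s < 1 mm/s threshold
        fld = _plane_field(axial)
        v_bi, dur = bidirectional_velocity(fld)
        assert v_bi == pytest.approx(0.08)
        assert dur == 0.0
        assert BIDIRECTIONAL_THRESHOLD == pytest.approx(0.1)

    def test_high_womersley_annulus_reversal_duration_positive(
            self, annulus_section, annulus_mesh, fluid):
        from csfhydro.solver import solve_waveform
        wf = make_flow_waveform(stroke_volume=None, harmonics=[(1, 2.0, 0.0)])
        sol = solve_waveform(annulus_section, fluid, wf, mesh=annulus_mesh)
        fld = sol.time_domain(n_steps=100)
        v_bi, dur = bidirectional_velocity(fld)
        assert v_bi > 0
        assert dur > 0


class TestReynolds:
    class _Stub:
        area = 61.0
        hydraulic_diameter = 10.0

    def test_zero_flow(self, fluid):
        wf = make_flow_waveform(stroke_volume=None, harmonics=[(1, 1e-30, 0)])
        assert reynolds_internal(wf, self._Stub(), fluid) < 1e-20

    def test_reference_arithmetic(self, fluid):
        wf = make_flow_waveform(stroke_volume=None,
                                harmonics=[(1, 0.793, 0.0)], n_samples=400)
        re = reynolds_internal(wf, self._Stub(), fluid)
        expected = (0.793e-6 / 61e-6) * 10e-3 / fluid.kinematic_viscosity
        assert re == pytest.approx(expected, rel=1e-3)
        assert re == pytest.approx(185, rel=2e-2)

    def test_doubling_flow_doubles_re(self, fluid):
        wf1 = make_flow_waveform(stroke_volume=0.5)
        wf2 = make_flow_waveform(stroke_volume=1.0)
        r1 = reynolds_internal(wf1, self._Stub(), fluid)
        r2 = reynolds_internal(wf2, self._Stub(), fluid)
        assert r2 == pytest.approx(2 * r1, rel=1e-9)

    def test_external_reference_arithmetic(self, fluid):
        fld = _plane_field(np.full((4, 5), -1.2))    # 1.2 cm/s everywhere
        spec = ExternalFlowSpec("root", 12.0, (0.0, 0.0, 0.0))
        re = reynolds_external(fld, spec, fluid)
        assert re == pytest.approx(0.012 * 0.012 / fluid.kinematic_viscosity,
                                   rel=1e-9)
        assert re == pytest.approx(205, rel=2e-2)

    def test_external_linear_in_length_and_speed(self, fluid):
        fld1 = _plane_field(np.full((4, 5), -1.0))
        fld2 = _plane_field(np.full((4, 5), -2.0))
        s1 = ExternalFlowSpec("a", 6.0, (0, 0, 0))
        s2 = ExternalFlowSpec("a", 12.0, (0, 0, 0))
        base = reynolds_external(fld1, s1, fluid)
        assert reynolds_external(fld1, s2, fluid) == pytest.approx(2 * base)
        assert reynolds_external(fld2, s1, fluid) == pytest.approx(2 * base)

    def test_probe_outside_domain_rejected(self, fluid):
        fld = _plane_field(np.ones((2, 3)))
        with pytest.raises(MetricError):
            reynolds_external(fld, ExternalFlowSpec("x", 5.0, (999, 0, 0)),
                              fluid)


class TestSecondaryFlow:
    def test_bounds_and_rotation_invariance(self):
        spec = SyntheticFieldSpec(axial_amplitude=2.0, uniform_inplane=(0.7, 0.4))
        fld, _ = make_synthetic_field(spec)
        sfp, peak = secondary_flow_parameter(fld)
        assert np.all((0 <= sfp) & (sfp <= 1))
        # rigid rotation of the in-plane axes
        th = 0.7
        rot = fld.velocity.copy()
        vx, vz = rot[:, :, 0].copy(), rot[:, :, 2].copy()
        rot[:, :, 0] = math.cos(th) * vx - math.sin(th) * vz
        rot[:, :, 2] = math.sin(th) * vx + math.cos(th) * vz
        fld2 = VelocityField(points=fld.points, times=fld.times,
                             velocity=rot, weights=fld.weights,
                             period=fld.period)
        sfp2, peak2 = secondary_flow_parameter(fld2)
        assert np.allclose(sfp, sfp2, atol=1e-12)

    def test_unit_rescaling_invariance(self):
        spec = SyntheticFieldSpec(axial_amplitude=1.0, uniform_inplane=(0.5, 0))
        fld, _ = make_synthetic_field(spec)
        scaled = VelocityField(points=fld.points * 1e-3, times=fld.times,
                               velocity=fld.velocity,
                               weights=fld.weights * 1e-6,
                               period=fld.period, attrs=fld.attrs)
        _, p1 = secondary_flow_parameter(fld)
        _, p2 = secondary_flow_parameter(scaled)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_volume_rejected(self):
        fld = _plane_field(np.ones((2, 3)))
        with pytest.raises(MetricError):
            secondary_flow_parameter(fld, y_range=(5.0, 6.0))


class TestWallShear:
    def test_linear_shear_is_exact(self, fluid):
        # v_t = k * d with k = 40 (cm/s)/mm: tau = mu * 400 1/s
        k = 40.0
        tau = wall_shear_from_samples(k * 0.1, k * 0.2, 0.1, fluid)
        assert tau == pytest.approx(fluid.dynamic_viscosity * k * 10, rel=1e-12)

    def test_one_sided_gradient_exact_for_quadratics(self):
        f = lambda s: 3 * s - 0.7 * s**2
        d = 0.13
        assert one_sided_wall_gradient(f(d), f(2 * d), d) == pytest.approx(3.0)

    def test_annular_poiseuille_within_one_percent(self, fluid):
        spec = SyntheticFieldSpec(axial_profile="annular_poiseuille",
                                  axial_time="steady", axial_amplitude=3.0,
                                  spacing=0.0625, n_steps=4)
        fld, gt = make_synthetic_field(spec)
        tau = wall_shear_stress_annulus(fld, fluid)
        assert tau == pytest.approx(gt.peak_wss, rel=1e-2)

    def test_zero_field_gives_zero(self, fluid):
        spec = SyntheticFieldSpec(axial_amplitude=0.0, axial_profile="none",
                                  n_steps=2)
        fld, _ = make_synthetic_field(spec)
        assert wall_shear_stress_annulus(fld, fluid) == 0.0

    def test_too_few_interior_layers_rejected(self, fluid):
        spec = SyntheticFieldSpec(r_inner=7.0, r_outer=8.0, spacing=0.6,
                                  n_steps=2)
        fld, _ = make_synthetic_field(spec)
        with pytest.raises(MetricError, match="layers"):
            wall_shear_stress_annulus(fld, fluid)

    def test_steady_poiseuille_pipe_closed_form(self, pipe_section, pipe_mesh,
                                                fluid):
        from csfhydro.solver import SectionSolution, solve_harmonic
        from csfhydro.mesh import assemble_p1
        wf = make_flow_waveform(stroke_volume=None, harmonics=[(1, 1, 0)])
        h = solve_harmonic(pipe_section, fluid, 0.0, 1.0, mesh=pipe_mesh)
        _, M = assemble_p1(pipe_mesh)
        sol = SectionSolution(section=pipe_section, mesh=pipe_mesh,
                              fluid=fluid, waveform=wf, harmonics=[h],
                              node_area=np.asarray(M.sum(axis=1)).ravel())
        tau = wall_shear_stress_solution(sol, np.array([0.0]))
        tau_exact = 4 * fluid.dynamic_viscosity * 1e-6 / (math.pi * 0.005**3)
        assert tau == pytest.approx(tau_exact, rel=1e-2)


class TestPressureStats:
    def test_sinusoid_peak(self):
        import pandas as pd
        t = np.arange(100) / 100
        df = pd.DataFrame({"t_s": t, "A-B": 3.5 * np.sin(2 * np.pi * t)})
        out = pressure_gradient_stats(df)
        assert out.loc[out.segment == "A-B", "dP_peak_Pa"].iloc[0] == \
            pytest.approx(3.5, rel=1e-3)

    def test_segment_sum_telescopes_and_triangle_inequality(self):
        import pandas as pd
        t = np.arange(100) / 100
        a = np.sin(2 * np.pi * t)
        b = np.sin(2 * np.pi * t + 2.0)
        df = pd.DataFrame({"t_s": t, "A-B": a, "B-C": b, "A-C": a + b})
        out = pressure_gradient_stats(df).set_index("segment").dP_peak_Pa
        assert out["A-C"] <= out["A-B"] + out["B-C"] + 1e-12


class TestVortexFrequency:
    def test_constant_series_flags_flat_spectrum(self):
        res = vortex_frequency(np.ones(200), period=1.0, dt=0.01)
        assert res.flat_spectrum and res.frequency_hz == 0.0

    def test_dominant_tone_detected(self):
        t = np.arange(400) * 0.01
        x = np.sin(2 * np.pi * 1.0 * t) + 0.2 * np.sin(2 * np.pi * 5.0 * t)
        res = vortex_frequency(x, period=1.0, dt=0.01)
        assert res.frequency_hz == pytest.approx(1.0)
        assert res.cardiac_frequency_hz == 1.0

    def test_shedding_tone_recovered_within_one_bin(self):
        t = np.arange(400) * 0.01                  # 4 cycles, bin = 0.25 Hz
        x = 1.0 * np.sin(2 * np.pi * t) + 1.5 * np.sin(2 * np.pi * 2.36 * t)
        res = vortex_frequency(x, period=1.0, dt=0.01, non_cardiac=True)
        assert abs(res.frequency_hz - 2.36) <= 0.25

    def test_short_series_rejected(self):
        with pytest.raises(MetricError):
            vortex_frequency(np.ones(50), period=1.0, dt=0.01)
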