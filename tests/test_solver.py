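"""Oscillatory solver: closed-form oracles, flux matching, linearity."""

import math

import numpy as np
import pytest
from shapely.geometry import Point

from csfhydro.anatomy import CrossSection, StationParams, build_geometry
from csfhydro.mesh import MeshError, TriMesh, assemble_p1, triangulate
from csfhydro.solver import (
    MESH_LEVELS,
    SolverError,
    mesh_section,
    solve_harmonic,
    solve_waveform,
    womersley_number,
)
from csfhydro.synthetic import make_flow_waveform

from conftest import ANNULUS_RI, ANNULUS_RO, PIPE_RADIUS, rel_l2
from oracles import (
    poiseuille_annulus,
    poiseuille_annulus_conductance,
    womersley_annulus,
    womersley_annulus_flux,
    womersley_pipe,
    womersley_pipe_flux,
)

OMEGA = 2 * math.pi     # fundamental cardiac harmonic at T = 1 s


class TestMesh:
    def test_circle_mesh_recovers_area(self, pipe_mesh):
        assert pipe_mesh.total_area() == pytest.approx(
            math.pi * PIPE_RADIUS**2, rel=2e-3)

    def test_boundary_normals_point_inward(self, pipe_mesh):
        b = pipe_mesh.boundary
        pts = pipe_mesh.points[b]
        nrm = pipe_mesh.boundary_normals[b]
        # for a circle, the inward normal is -r_hat
        rhat = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        assert np.allclose(np.sum(nrm * rhat, axis=1), -1.0, atol=1e-2)

    def test_stiffness_annihilates_constants(self, pipe_mesh):
        K, M = assemble_p1(pipe_mesh)
        ones = np.ones(pipe_mesh.n_nodes)
        assert np.abs(K @ ones).max() < 1e-10
        assert M.sum() == pytest.approx(pipe_mesh.total_area(), rel=1e-12)

    def test_empty_polygon_rejected(self):
        from shapely.geometry import Polygon
        with pytest.raises(MeshError):
            triangulate(Polygon())

    def test_obstructed_section_partitions_into_channels(self):
        from csfhydro.mesh import connected_component_count
        geo = build_geometry(with_nrdl=True)
        msh = mesh_section(geo.sections["C5"], *MESH_LEVELS["coarse"])
        assert connected_component_count(msh) > 1


class TestWomersleyOracle:
    def test_pipe_profile_matches_bessel_closed_form(
            self, pipe_section, pipe_mesh, fluid):
        sol = solve_harmonic(pipe_section, fluid, OMEGA, 2.0 + 0j,
                             mesh=pipe_mesh)
        r = np.hypot(pipe_mesh.points[:, 0], pipe_mesh.points[:, 1]) * 1e-3
        flux = womersley_pipe_flux(PIPE_RADIUS * 1e-3, OMEGA,
                                   fluid.kinematic_viscosity, fluid.density)
        G = 2.0e-6 / flux
        u_exact = womersley_pipe(r, PIPE_RADIUS * 1e-3, OMEGA,
                                 fluid.kinematic_viscosity, fluid.density, G)
        assert rel_l2(sol.u, u_exact) < 1e-3
        assert abs(sol.G - G) / abs(G) < 1e-2

    def test_annulus_profile_matches_bessel_closed_form(
            self, annulus_section, annulus_mesh, fluid):
        sol = solve_harmonic(annulus_section, fluid, OMEGA, 2.0 + 0j,
                             mesh=annulus_mesh)
        r = np.hypot(annulus_mesh.points[:, 0], annulus_mesh.points[:, 1]) * 1e-3
        flux = womersley_annulus_flux(ANNULUS_RI * 1e-3, ANNULUS_RO * 1e-3,
                                      OMEGA, fluid.kinematic_viscosity,
                                      fluid.density)
        G = 2.0e-6 / flux
        u_exact = womersley_annulus(r, ANNULUS_RI * 1e-3, ANNULUS_RO * 1e-3,
                                    OMEGA, fluid.kinematic_viscosity,
                                    fluid.density, G)
        assert rel_l2(sol.u, u_exact) < 1e-3

    def test_steady_annulus_is_poiseuille(self, annulus_section, annulus_mesh,
                                          fluid):
        sol = solve_harmonic(annulus_section, fluid, 0.0, 1.0, mesh=annulus_mesh)
        mu = fluid.dynamic_viscosity
        cond = poiseuille_annulus_conductance(ANNULUS_RI * 1e-3,
                                              ANNULUS_RO * 1e-3, mu)
        G_exact = 1.0e-6 / cond
        assert sol.G == pytest.approx(G_exact, rel=2e-3)
        r = np.hypot(annulus_mesh.points[:, 0], annulus_mesh.points[:, 1]) * 1e-3
        u_exact = poiseuille_annulus(np.maximum(r, 1e-9), ANNULUS_RI * 1e-3,
                                     ANNULUS_RO * 1e-3, mu, np.real(sol.G))
        assert rel_l2(np.real(sol.u), u_exact) < 1e-3

    def test_error_improves_under_refinement(self, pipe_section, fluid):
        errs = []
        for level in ("coarse", "medium", "fine"):
            hw, hc, g = MESH_LEVELS[level]
            msh = mesh_section(pipe_section, hw, hc, g)
            sol = solve_harmonic(pipe_section, fluid, OMEGA, 2.0 + 0j, mesh=msh)
            r = np.hypot(msh.points[:, 0], msh.points[:, 1]) * 1e-3
            flux = womersley_pipe_flux(PIPE_RADIUS * 1e-3, OMEGA,
                                       fluid.kinematic_viscosity, fluid.density)
            G = 2.0e-6 / flux
            u_exact = womersley_pipe(r, PIPE_RADIUS * 1e-3, OMEGA,
                                     fluid.kinematic_viscosity,
                                     fluid.density, G)
            errs.append(rel_l2(sol.u, u_exact))
        assert errs[0] > errs[1] > errs[2]


class TestFluxAndLinearity:
    def test_zero_flux_harmonic_is_identically_zero(self, pipe_section,
                                                    pipe_mesh, fluid):
        sol = solve_harmonic(pipe_section, fluid, OMEGA, 0.0, mesh=pipe_mesh)
        assert np.all(sol.u == 0)
        assert sol.G == 0

    def test_no_slip_on_every_boundary_node(self, annulus_section,
                                            annulus_mesh, fluid):
        sol = solve_harmonic(annulus_section, fluid, OMEGA, 2.0 + 0j,
                             mesh=annulus_mesh)
        assert np.abs(sol.u[annulus_mesh.boundary]).max() == 0.0

    def test_flux_matches_waveform_at_all_steps(self, annulus_section, fluid):
        wf = make_flow_waveform()
        sol = solve_waveform(annulus_section, fluid, wf,
                             h_wall=0.08, h_core=0.35, growth=1.3)
        t = np.arange(100) * wf.period / 100
        q = wf.evaluate(t)
        assert np.max(np.abs(sol.flux(t) - q)) <= 1e-6 * np.max(np.abs(q))

    def test_linearity_in_flux_amplitude(self, pipe_section, pipe_mesh, fluid):
        s1 = solve_harmonic(pipe_section, fluid, OMEGA, 1.0 + 0j, mesh=pipe_mesh)
        s3 = solve_harmonic(pipe_section, fluid, OMEGA, 3.0 + 0j, mesh=pipe_mesh)
        assert np.allclose(s3.u, 3 * s1.u, rtol=1e-12, atol=1e-16)
        assert s3.G == pytest.approx(3 * s1.G, rel=1e-12)

    def test_superposition_of_harmonics(self, pipe_section, pipe_mesh, fluid):
        wf = make_flow_waveform(stroke_volume=None,
                                harmonics=[(1, 1.0, 0.2), (2, 0.5, 1.0)])
        sol = solve_waveform(pipe_section, fluid, wf, mesh=pipe_mesh)
        t = np.arange(32) * wf.period / 32
        combined = sol.velocity(t)
        parts = np.zeros_like(combined)
        for h in sol.harmonics:
            s = solve_harmonic(pipe_section, fluid, h.omega, h.Q,
                               mesh=pipe_mesh, n=h.n)
            parts += np.real(np.exp(1j * h.omega * t)[:, None] * s.u[None, :])
        assert np.allclose(combined, parts, rtol=1e-12, atol=1e-15)

    def test_periodic_closure(self, pipe_section, pipe_mesh, fluid):
        wf = make_flow_waveform()
        sol = solve_waveform(pipe_section, fluid, wf, mesh=pipe_mesh)
        v0 = sol.velocity(np.array([0.0]))
        vT = sol.velocity(np.array([wf.period]))
        assert np.abs(v0 - vT).max() < 1e-9

    def test_near_wall_reversal_at_high_womersley(self, annulus_section,
                                                  annulus_mesh, fluid):
        """Annular-Womersley phase lead: when the bulk flux crosses zero the
        near-wall fluid already moves the other way (checked against the
        closed-form annulus profile)."""
        sol = solve_harmonic(annulus_section, fluid, OMEGA, 2.0 + 0j,
                             mesh=annulus_mesh)
        alpha = sol.alpha
        assert alpha > 10
        t = np.linspace(0, 1, 400)
        q_t = np.real(sol.Q * np.exp(1j * OMEGA * t))
        k0 = int(np.argmin(np.abs(q_t)))          # flux-reversal instant
        v = np.real(sol.u * np.exp(1j * OMEGA * t[k0]))
        r = np.hypot(annulus_mesh.points[:, 0], annulus_mesh.points[:, 1])
        near_wall = (~annulus_mesh.boundary) & ((r > 7.6) | (r < 4.4))
        core = np.abs(r - 6.0) < 0.4
        assert v[near_wall].max() * v[near_wall].min() < 0 or \
            np.sign(np.median(v[near_wall])) != np.sign(np.median(v[core]))
        # independent oracle: closed form shows the same opposition
        rr = np.array([4.3e-3, 6.0e-3])
        flux = womersley_annulus_flux(ANNULUS_RI * 1e-3, ANNULUS_RO * 1e-3,
                                      OMEGA, fluid.kinematic_viscosity,
                                      fluid.density)
        u_cf = womersley_annulus(rr, ANNULUS_RI * 1e-3, ANNULUS_RO * 1e-3,
                                 OMEGA, fluid.kinematic_viscosity,
                                 fluid.density, 2.0e-6 / flux)
        v_cf = np.real(u_cf * np.exp(1j * OMEGA * t[k0]))
        assert np.sign(v_cf[0]) != np.sign(v_cf[1])


class TestObstructionResistance:
    def test_obstruction_increases_pressure_gradient_every_harmonic(self, fluid):
        outer = Point(0, 0).buffer(8.0, quad_segs=64)
        inner = Point(0, 0).buffer(4.0, quad_segs=64)
        base = outer.difference(inner)
        hole = Point(6, 0).buffer(1.0, quad_segs=32)
        params = StationParams("x", 8.0, 4.0)
        sec0 = CrossSection("x", params, base)
        sec1 = CrossSection("x", params, base.difference(hole),
                            obstructions=[hole])
        for n in (1, 2, 3):
            g0 = solve_harmonic(sec0, fluid, n * OMEGA, 1.0 + 0j,
                                mesh=mesh_section(sec0, *MESH_LEVELS["coarse"]))
            g1 = solve_harmonic(sec1, fluid, n * OMEGA, 1.0 + 0j,
                                mesh=mesh_section(sec1, *MESH_LEVELS["coarse"]))
            assert abs(g1.G) > abs(g0.G)


class TestWomersleyNumber:
    def test_zero_frequency(self, pipe_section, fluid):
        assert womersley_number(pipe_section, fluid, 0.0) == 0.0

    def test_reference_value(self, fluid):
        # D_h = 10 mm at 1 Hz with nu ~= 7.02e-7 m^2/s
        circle = Point(0, 0).buffer(5.0, quad_segs=128)
        sec = CrossSection("c", StationParams("c", 5.0, 0.01), circle)
        alpha = womersley_number(sec, fluid, 2 * math.pi)
        expected = 0.005 * math.sqrt(2 * math.pi / fluid.kinematic_viscosity)
        assert alpha == pytest.approx(expected, rel=1e-3)
        assert alpha == pytest.approx(14.96, rel=5e-3)

    def test_sqrt_omega_scaling(self, pipe_section, fluid):
        a1 = womersley_number(pipe_section, fluid, 1.0)
        a4 = womersley_number(pipe_section, fluid, 4.0)
        assert a4 == pytest.approx(2 * a1, rel=1e-12)


def test_zero_waveform_rejected(pipe_section, pipe_mesh, fluid):
    from csfhydro.synthetic import FlowWaveform
    wf = FlowWaveform(1.0, np.zeros(32))
    with pytest.raises(SolverError):
        solve_waveform(pipe_section, fluid, wf, mesh=pipe_mesh)
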