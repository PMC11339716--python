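"""Solver tests: partition and window impedances, assembly, oracles.

The analytic oracles here are independent of the solver path: the window
stiffness is checked against the uniform-load clamped-plate deflection
formula, the degenerate two-segment model against a hand-derived ladder
circuit, and the full solution against a dense LU factorization of the
assembled system.
"""

import dataclasses

import numpy as np
import pytest

import cochlearbox as cb
from cochlearbox.fixtures import default_geometry, default_materials
from cochlearbox.material_laws import DampingSpec, IsotropicElasticity
from cochlearbox.metrics import extract_cf, greenwood_position
from cochlearbox.solver import (
    StimulusSpec,
    assemble,
    conservation_check,
    make_stimulus,
    partition_impedance,
    partition_mass,
    partition_stiffness,
    solve,
    window_boundary_impedance,
)

FREQS = (125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0)


class TestPartitionImpedance:
    def test_resonance_is_purely_resistive(self, geometry, materials, stiffness_const):
        """At 2*pi*f = sqrt(k/m) the reactances cancel: z_p = r + c."""
        x = 0.4 * geometry.bm_length
        m = partition_mass(x, geometry, fluid=materials.fluid)
        k = partition_stiffness(x, geometry, materials.bm, stiffness_const=stiffness_const)
        f_res = float(np.sqrt(k / m)) / (2 * np.pi)
        z = partition_impedance(
            x, f_res, materials.bm, geometry, materials.damping,
            stiffness_const=stiffness_const, fluid=materials.fluid,
        )
        r = materials.damping.alpha * m + materials.damping.beta * k
        assert z.imag == pytest.approx(0.0, abs=1e-6 * abs(z))
        assert z.real == pytest.approx(float(r) + materials.damping.c, rel=1e-12)

    def test_stiffness_strictly_decreasing(self, geometry, materials, stiffness_const):
        x = geometry.segment_centers()
        k = partition_stiffness(x, geometry, materials.bm, stiffness_const=stiffness_const)
        assert np.all(np.diff(k) < 0)

    def test_undamped_is_purely_reactive(self, geometry, materials, stiffness_const):
        undamped = DampingSpec(alpha=0.0, beta=0.0, c=0.0)
        z = partition_impedance(
            0.01, 700.0, materials.bm, geometry, undamped,
            stiffness_const=stiffness_const, fluid=materials.fluid,
        )
        assert z.real == 0.0

    def test_nonpositive_frequency_rejected(self, geometry, materials, stiffness_const):
        with pytest.raises(ValueError):
            partition_impedance(
                0.01, 0.0, materials.bm, geometry, materials.damping,
                stiffness_const=stiffness_const,
            )


class TestWindowImpedance:
    def test_rwm_matches_clamped_plate_deflection_oracle(self, materials):
        """Low-frequency |z_rw| vs the uniform-load centre-deflection formula.

        Oracle: w0 = q a^4 / (64 D), mean deflection w0/3, volume compliance
        C = area * (w0/3) / q, |z| ~ 1/(omega C) in the stiffness regime.
        """
        g = default_geometry()
        a = np.sqrt(g.a_rw / np.pi)
        E, nu, t = materials.rwm.E, materials.rwm.nu, g.rwm_thickness
        D = E * t**3 / (12 * (1 - nu**2))
        w0_per_q = a**4 / (64 * D)
        compliance = g.a_rw * w0_per_q / 3.0
        f = 5.0  # far below the window resonance
        oracle = 1.0 / (2 * np.pi * f * compliance)
        z = window_boundary_impedance(
            materials.rwm, g.a_rw, g.rwm_thickness, "RWM-plate", f,
            fluid=materials.fluid, damping=materials.damping,
        )
        assert abs(z) == pytest.approx(oracle, rel=0.01)

    def test_ossified_limit_is_rigid(self, materials):
        g = default_geometry()
        z_n = window_boundary_impedance(
            materials.rwm, g.a_rw, g.rwm_thickness, "RWM-plate", 1000.0,
            fluid=materials.fluid,
        )
        z_oss = window_boundary_impedance(
            IsotropicElasticity(E=2.0e11, nu=materials.rwm.nu),
            g.a_rw, g.rwm_thickness, "RWM-plate", 1000.0, fluid=materials.fluid,
        )
        assert abs(z_oss) > 1e3 * abs(z_n)

    def test_x100_scales_stiffness_part_by_100(self, materials):
        g = default_geometry()
        f = 5.0  # stiffness-dominated regime
        z_n = window_boundary_impedance(
            materials.sal, g.a_fp, g.sal_thickness, "SAL-annulus", f,
            attached_mass=g.stapes_mass, fluid=materials.fluid,
            annulus_width=g.sal_annulus_width,
        )
        z_100 = window_boundary_impedance(
            IsotropicElasticity(E=materials.sal.E * 100, nu=materials.sal.nu),
            g.a_fp, g.sal_thickness, "SAL-annulus", f,
            attached_mass=g.stapes_mass, fluid=materials.fluid,
            annulus_width=g.sal_annulus_width,
        )
        assert z_100.imag == pytest.approx(100 * z_n.imag, rel=1e-3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="unknown-window"),
            dict(area=-1e-6),
            dict(thickness=0.0),
            dict(f=-10.0),
        ],
    )
    def test_nonphysical_inputs_rejected(self, materials, kwargs):
        g = default_geometry()
        base = dict(
            membrane=materials.rwm, area=g.a_rw, thickness=g.rwm_thickness,
            kind="RWM-plate", f=1000.0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            window_boundary_impedance(**base)


class TestAssemblyAndSolve:
    def test_zero_source_gives_zero_solution(self, geometry, materials, stiffness_const):
        model = assemble(geometry, materials, 1000.0, stiffness_const=stiffness_const)
        silent = StimulusSpec(pathway="forward", frequency=1000.0, level=-np.inf, force=0.0)
        sol = solve(model, silent)
        assert np.all(sol.d == 0)
        assert sol.u_ow == 0

    def test_one_assembly_serves_both_pathways(self, geometry, materials, stiffness_const):
        """The system matrix is stimulus-independent; only sources differ."""
        model = assemble(geometry, materials, 1000.0, stiffness_const=stiffness_const)
        fwd = solve(model, make_stimulus("forward", 1000.0, geometry))
        rev = solve(model, make_stimulus("reverse", 1000.0, geometry))
        assert fwd.pathway == "forward" and rev.pathway == "reverse"
        assert fwd.u_ow != rev.u_ow

    def test_residual_against_dense_factorization(self, geometry, materials, stiffness_const):
        model = assemble(geometry, materials, 1000.0, stiffness_const=stiffness_const)
        sol = solve(model, make_stimulus("forward", 1000.0, geometry))
        assert sol.residual < 1e-10
        # independent dense LU of the same assembled system
        n = geometry.n_segments
        b = np.zeros(2 * n, dtype=complex)
        b[0] = cb.spl_to_pressure(86.0) / model.z_ow
        dense = np.linalg.solve(model.matrix.toarray(), b)
        assert np.allclose(dense[:n], sol.p_sv, rtol=1e-8)
        assert np.allclose(dense[n:], sol.p_st, rtol=1e-8)

    def test_linearity(self, geometry, materials, stiffness_const):
        model = assemble(geometry, materials, 500.0, stiffness_const=stiffness_const)
        lo = solve(model, StimulusSpec("forward", 500.0, 66.0, 0.0))
        hi = solve(model, StimulusSpec("forward", 500.0, 86.0, 0.0))
        assert np.allclose(hi.d, 10.0 * lo.d, rtol=1e-12)
        assert hi.u_rw == pytest.approx(10.0 * lo.u_rw, rel=1e-12)

    def test_reciprocity(self, geometry, materials, stiffness_const):
        """Symmetric network: equal-pressure forward and reverse stimulation
        produce identical BM magnitudes, and the matrix is symmetric."""
        small = dataclasses.replace(geometry, n_segments=40)
        model = assemble(small, materials, 800.0, stiffness_const=stiffness_const)
        asym = abs(model.matrix - model.matrix.T)
        assert asym.max() == 0.0
        fwd = solve(model, StimulusSpec("forward", 800.0, 86.0, 0.0))
        rev = solve(model, StimulusSpec("reverse", 800.0, 86.0, 0.0))
        assert np.allclose(np.abs(rev.d), np.abs(fwd.d), rtol=1e-10)

    def test_two_segment_degenerate_model_matches_ladder_circuit(self, materials):
        """Hand-derived two-rung ladder: Z_net = Z_bm0 || (Z_sv + Z_bm1 + Z_st),
        u = p / (z_ow + z_rw + Z_net), displacement from the rung dividers."""
        g = dataclasses.replace(default_geometry(), n_segments=2)
        f, C = 900.0, 5000.0
        model = assemble(g, materials, f, stiffness_const=C, include_helicotrema=False)
        omega = 2 * np.pi * f
        dx = g.bm_length / 2
        x = g.segment_centers()
        w = np.asarray(g.bm_width(x / g.bm_length))
        z_bm = model.z_p * 1.0 / (w * dx)  # rung impedances (volume-velocity)
        z_sv = 1j * omega * materials.fluid.rho * dx / g.scala_vestibuli_area \
            + 8 * np.pi * materials.fluid.mu * dx / g.scala_vestibuli_area**2
        z_st = 1j * omega * materials.fluid.rho * dx / g.scala_tympani_area \
            + 8 * np.pi * materials.fluid.mu * dx / g.scala_tympani_area**2
        z_far = z_sv + z_bm[1] + z_st
        z_net = z_bm[0] * z_far / (z_bm[0] + z_far)
        p = cb.spl_to_pressure(86.0)
        u = p / (model.z_ow + model.z_rw + z_net)
        p_diff0 = u * z_net
        u_far = p_diff0 / z_far
        p_diff1 = u_far * z_bm[1]
        sol = solve(model, StimulusSpec("forward", f, 86.0, 0.0))
        assert sol.u_ow == pytest.approx(u, rel=1e-8)
        assert sol.p_diff[0] == pytest.approx(p_diff0, rel=1e-8)
        assert sol.p_diff[1] == pytest.approx(p_diff1, rel=1e-8)
        assert conservation_check(sol) == 0.0

    def test_mismatched_stimulus_frequency_rejected(self, geometry, materials, stiffness_const):
        model = assemble(geometry, materials, 1000.0, stiffness_const=stiffness_const)
        with pytest.raises(ValueError, match="frequency"):
            solve(model, make_stimulus("forward", 2000.0, geometry))

    def test_nonpositive_frequency_rejected(self, geometry, materials):
        with pytest.raises(ValueError):
            assemble(geometry, materials, -100.0, stiffness_const=5000.0)


class TestTravelingWave:
    def test_cf_moves_apexward_as_frequency_decreases(self, geometry, materials, stiffness_const):
        for pathway in ("forward", "reverse"):
            locs = []
            for f in FREQS:
                model = assemble(geometry, materials, f, stiffness_const=stiffness_const)
                sol = solve(model, make_stimulus(pathway, f, geometry))
                locs.append(extract_cf(np.abs(sol.d))[0])
            assert np.all(np.diff(locs) < 0)  # ordered 125 Hz (apical) -> 4 kHz (basal)

    def test_grid_convergence_under_2_percent(self, geometry, materials, stiffness_const):
        fine = dataclasses.replace(geometry, n_segments=2 * geometry.n_segments)
        for f in (125.0, 1000.0, 4000.0):
            sols = []
            for g in (geometry, fine):
                model = assemble(g, materials, f, stiffness_const=stiffness_const)
                sols.append(solve(model, make_stimulus("forward", f, g)))
            peak_coarse = np.max(np.abs(sols[0].d))
            peak_fine = np.max(np.abs(sols[1].d))
            assert abs(peak_fine - peak_coarse) / peak_coarse < 0.02

    def test_greenwood_calibration_places_1khz_peak(self, geometry, materials, stiffness_const):
        model = assemble(geometry, materials, 1000.0, stiffness_const=stiffness_const)
        sol = solve(model, make_stimulus("forward", 1000.0, geometry))
        loc, _ = extract_cf(np.abs(sol.d))
        assert loc == pytest.approx(greenwood_position(1000.0), abs=1e-3)

    def test_ossified_window_drops_velocity_40_db(self, geometry, materials, stiffness_const):
        f = 1000.0
        normal = solve(
            assemble(geometry, materials, f, stiffness_const=stiffness_const),
            make_stimulus("forward", f, geometry),
        )
        for scenario, attr in (("sal_ossified", "u_ow"), ("rwm_ossified", "u_rw")):
            staged = solve(
                assemble(
                    geometry, materials, f,
                    scenario=cb.make_scenario(scenario),
                    stiffness_const=stiffness_const,
                ),
                make_stimulus("forward", f, geometry),
            )
            drop = 20 * np.log10(abs(getattr(normal, attr)) / abs(getattr(staged, attr)))
            assert drop >= 40.0

    def test_conservation_scale_invariant(self, geometry, materials, stiffness_const):
        model = assemble(geometry, materials, 250.0, stiffness_const=stiffness_const)
        lo = solve(model, StimulusSpec("forward", 250.0, 66.0, 0.0))
        hi = solve(model, StimulusSpec("forward", 250.0, 106.0, 0.0))
        assert conservation_check(lo) == conservation_check(hi)
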