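"""Cable solver: discretization, field coupling, integration accuracy."""
import math

import numpy as np
import pytest
import scipy.linalg

from efneuron.biophysics import Biophysics, MembraneState, PassiveParams
from efneuron.errors import ParameterError, SuprathresholdFieldError
from efneuron.field_solver import (FieldStimulus, SolverConfig, build_system,
                                   extracellular_potentials, field_drive,
                                   init_system_steady_state, simulate,
                                   simulate_system, steady_state_polarization)
from efneuron.morphology import MorphologyTree, Point2D, SectionSpec
from efneuron.system import axial_conductance, compartment_count


def straight_fiber(length, diameter):
    return MorphologyTree([SectionSpec("soma", "soma",
                                       Point2D(0, -length / 2),
                                       Point2D(0, length / 2), diameter)])


class TestDiscretization:
    @pytest.mark.parametrize("L,dx,n", [(10, 10, 1), (50, 10, 5), (8, 10, 1),
                                        (25, 10, 3), (100, 10, 11)])
    def test_odd_compartment_counts(self, L, dx, n):
        assert compartment_count(L, dx) == n

    def test_default_cell_compartments(self, default_tree, kinetics):
        system = build_system(default_tree, kinetics, 10.0)
        assert system.n == 1 + 5 + 4 + 8
        assert system.parent[0] == -1
        assert np.all(system.parent[1:] < np.arange(1, system.n))


class TestAxialConductance:
    def test_diameter_squared_scaling(self):
        g1 = axial_conductance(2.0, 10.0, 2.0, 10.0, 80.0)
        g2 = axial_conductance(4.0, 10.0, 4.0, 10.0, 80.0)
        assert g2 == pytest.approx(4.0 * g1)

    def test_inverse_length_scaling(self):
        g1 = axial_conductance(2.0, 10.0, 2.0, 10.0, 80.0)
        g2 = axial_conductance(2.0, 20.0, 2.0, 20.0, 80.0)
        assert g2 == pytest.approx(0.5 * g1)

    def test_unequal_half_compartments_match_hand_series(self):
        # independent series-resistor computation in SI units
        ra = 80.0 * 1e-2            # Ohm*m
        d1, dx1, d2, dx2 = 1.0e-6, 8.0e-6, 10.0e-6, 10.0e-6  # m
        r1 = ra * dx1 / (math.pi * d1 ** 2 / 4.0)   # Ohm, full compartment
        r2 = ra * dx2 / (math.pi * d2 ** 2 / 4.0)
        g_si = 1.0 / (r1 / 2.0 + r2 / 2.0)          # S
        g = axial_conductance(1.0, 8.0, 10.0, 10.0, 80.0)  # uS
        assert g == pytest.approx(g_si * 1e6, rel=1e-12)

    def test_adjacency_required(self, default_tree, kinetics):
        system = build_system(default_tree, kinetics, 10.0)
        i, j = 0, 1
        assert system.axial_conductance_between(i, j) > 0
        with pytest.raises(ParameterError):
            system.axial_conductance_between(2, 4)


class TestExtracellularPotentials:
    def test_zero_field(self, default_tree, kinetics):
        system = build_system(default_tree, kinetics, 10.0)
        assert np.all(extracellular_potentials(system, 0.0) == 0.0)

    def test_axial_gradient(self, passive):
        fiber = straight_fiber(210.0, 2.0)  # 21 compartments, centers on a 10 μm grid
        system = build_system(fiber, passive, 10.0)
        v_ext = extracellular_potentials(system, 50.0)
        i = int(np.flatnonzero(np.isclose(system.y, -50.0))[0])
        j = int(np.flatnonzero(np.isclose(system.y, 50.0))[0])
        # 100 um along y at 50 mV/mm -> 5 mV
        assert v_ext[j] - v_ext[i] == pytest.approx(5.0)

    def test_perpendicular_element_sees_no_difference(self, passive):
        horiz = MorphologyTree([SectionSpec(
            "soma", "soma", Point2D(-50, 0), Point2D(50, 0), 2.0)])
        system = build_system(horiz, passive, 10.0)
        v_ext = extracellular_potentials(system, 50.0)
        assert np.allclose(np.diff(v_ext), 0.0)

    def test_gauge_invariance_of_drive(self, default_tree, kinetics):
        system = build_system(default_tree, kinetics, 10.0)
        v_ext = extracellular_potentials(system, 123.0)
        d0 = field_drive(system, v_ext)
        d1 = field_drive(system, v_ext + 77.7)
        assert np.allclose(d0, d1, atol=1e-12)


class TestIntegrationAccuracy:
    def test_two_compartment_step_matches_matrix_exponential(self):
        """One implicit step (with refinement) vs the exact linear solution."""
        pas = PassiveParams()
        bp = Biophysics.passive_only(pas)
        tree = MorphologyTree([
            SectionSpec("soma", "soma", Point2D(0, 0), Point2D(0, 10), 2.0),
            SectionSpec("axon", "axon", Point2D(0, 0), Point2D(0, -10), 2.0,
                        parent="soma", attach_end="proximal"),
        ])
        system = build_system(tree, bp, 10.0)
        assert system.n == 2
        g = system.g_ax[1]
        gl, C, el = system.g_leak, system.C, system.e_leak
        A = np.array([[-(gl[0] + g) / C[0], g / C[0]],
                      [g / C[1], -(gl[1] + g) / C[1]]])
        b = np.array([gl[0] * el / C[0], gl[1] * el / C[1]])
        v0 = np.array([-60.0, -70.0])
        dt = 1e-7  # small against the fast axial eigenvalue (~1.3/μs)
        # exact solution of v' = Av + b over one step:
        # v(dt) = e^{A dt} (v0 - v_inf) + v_inf with v_inf = -A^{-1} b
        v_inf = -np.linalg.solve(A, b)
        exact = scipy.linalg.expm(A * dt) @ (v0 - v_inf) + v_inf
        cfg = SolverConfig(dt=dt, duration=dt, record_sites="all")
        state = MembraneState(V=v0, gates={})
        trace = simulate_system(system, [], cfg, state=state)
        stepped = trace.V[:, -1]
        assert np.abs(stepped - exact).max() < 1e-6

    def test_steady_state_invariant_under_simulation(self, default_tree, kinetics):
        state = init_system_steady_state(
            build_system(default_tree, kinetics, 10.0))
        trace = simulate(default_tree, kinetics, [],
                         SolverConfig(duration=200.0), state=state)
        v = trace.site("soma", 0.5)
        assert np.abs(v - v[0]).max() < 0.1

    def test_passive_linearity_in_field(self, default_tree, passive):
        cfg = SolverConfig(duration=300.0)
        t1 = simulate(default_tree, passive,
                      [FieldStimulus(100.0, onset=50.0, offset=250.0)], cfg)
        t2 = simulate(default_tree, passive,
                      [FieldStimulus(200.0, onset=50.0, offset=250.0)], cfg)
        d1 = t1.site("soma", 0.5) - t1.site("soma", 0.5)[0]
        d2 = t2.site("soma", 0.5) - t2.site("soma", 0.5)[0]
        assert np.abs(2.0 * d1 - d2).max() <= 0.005 * np.abs(d2).max()

    def test_dt_self_convergence_passive(self, default_tree, passive):
        def run(dt):
            cfg = SolverConfig(dt=dt, duration=100.0)
            return simulate(default_tree, passive,
                            [FieldStimulus(100.0, onset=10.0, offset=90.0)],
                            cfg).site("soma", 0.5)
        v1, v2 = run(0.025), run(0.0125)
        assert np.abs(v2[::2] - v1).max() < 0.1

    def test_junction_conservation_active_run(self, default_tree, kinetics):
        system = build_system(default_tree, kinetics, 10.0)
        state = init_system_steady_state(system)
        _, resid = simulate_system(
            system, [FieldStimulus(300.0, onset=50.0, offset=250.0)],
            SolverConfig(duration=300.0), state=state, compute_residual=True)
        assert resid < 1e-9


class TestSteadyStatePolarization:
    lam = math.sqrt(28.0 * 1e3 * 2.0e-4 / (4 * 80.0)) * 1e4  # um, d = 2

    def fiber_and_bp(self):
        L = 2.0 * self.lam
        return straight_fiber(L, 2.0), Biophysics.passive_only(), L

    def test_sealed_fiber_matches_closed_form(self):
        fiber, bp, L = self.fiber_and_bp()
        E = 50.0
        cfg = SolverConfig(max_compartment_length=self.lam / 50.0,
                           steady_state_tolerance=1e-7)
        pol = steady_state_polarization(fiber, bp, E, cfg)
        # x measured toward the cathode: the anode-side end hyperpolarizes
        exact = -E / 1000.0 * self.lam * np.sinh(pol.y / self.lam) / \
            math.cosh(L / (2 * self.lam))
        err = np.abs(pol.delta_v - exact).max() / np.abs(exact).max()
        assert err < 0.01

    def test_fiber_midpoint_unpolarized(self):
        fiber, bp, _ = self.fiber_and_bp()
        cfg = SolverConfig(max_compartment_length=self.lam / 50.0,
                           steady_state_tolerance=1e-7)
        pol = steady_state_polarization(fiber, bp, 50.0, cfg)
        mid = np.argmin(np.abs(pol.y))
        assert abs(pol.delta_v[mid]) < 1e-6 * np.abs(pol.delta_v).max()

    def test_reversed_field_negates_profile(self, default_tree, passive):
        p1 = steady_state_polarization(default_tree, passive, 80.0)
        p2 = steady_state_polarization(default_tree, passive, -80.0)
        assert np.abs(p1.delta_v + p2.delta_v).max() <= \
            0.005 * np.abs(p1.delta_v).max()

    def test_suprathreshold_field_raises(self, default_tree, kinetics):
        with pytest.raises(SuprathresholdFieldError):
            steady_state_polarization(default_tree, kinetics, 400.0)

    def test_spatial_convergence_on_refinement(self, default_tree, passive):
        def midpoints(dx):
            pol = steady_state_polarization(
                default_tree, passive, 100.0,
                SolverConfig(max_compartment_length=dx))
            out = {}
            for (sec, arc), dv in zip(pol.sites, pol.delta_v):
                out.setdefault(sec, []).append((arc, dv))
            return {s: v[len(v) // 2][1] for s, v in out.items()}
        m1, m2 = midpoints(10.0), midpoints(5.0)
        scale = max(abs(v) for v in m1.values())
        assert max(abs(m1[s] - m2[s]) for s in m1) < 0.01 * scale


def test_trace_export_round_trip(tmp_path, default_tree, passive):
    from efneuron.field_solver import Trace
    trace = simulate(default_tree, passive,
                     [FieldStimulus(80.0, onset=10.0, offset=40.0)],
                     SolverConfig(duration=50.0,
                                  record_sites=(("soma", 0.5), ("axon", 0.5))))
    h5 = tmp_path / "trace.h5"
    trace.to_hdf5(h5)
    again = Trace.from_hdf5(h5)
    assert again.sites == trace.sites
    assert np.array_equal(again.V, trace.V)
    frame = trace.to_frame()
    assert set(frame.section) == {"soma", "axon"}
    assert len(frame) == trace.V.size


def test_divergence_reported_with_time_and_site(default_tree, kinetics):
    from efneuron.errors import SolverDivergenceError
    # a physically absurd field drives |V| past the plausibility guard
    with pytest.raises(SolverDivergenceError) as exc:
        simulate(default_tree, kinetics,
                 [FieldStimulus(1e7, onset=1.0, offset=50.0)],
                 SolverConfig(duration=60.0))
    assert exc.value.time_ms is not None and exc.value.site is not None
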