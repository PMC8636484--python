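"""Particle force model and Lagrangian integrator checks."""

import math

import numpy as np
import pytest

from carinaflow import (FluidProperties, NAMED_MEDIA, ParticleProperties,
                        SeedingSpec, TrackingConfig, drag_coefficient,
                        drag_force, gravity_force, particle_relaxation_time,
                        particle_reynolds, relaxation_oracle, seed_inlet,
                        step_particle, stokes_settling_velocity,
                        track_particles)
from carinaflow.flow import FlowField, P2Space
from carinaflow.particles import (GRAVITY, FlowInterpolator, ParticleState,
                                  segment_time_in_disc)

FLUID = NAMED_MEDIA["non_conditioned"]


def _uniform_field(mesh, u, fluid=FLUID, mean_speed=None):
    space = P2Space(mesh)
    vel = np.tile(np.asarray(u, dtype=float), (space.n_nodes, 1))
    from carinaflow import BoundaryConditions
    return FlowField(mesh=mesh, space=space, velocity=vel,
                     pressure=np.zeros(space.n_vertices), residuals=[0.0],
                     converged=True, fluid=fluid, bc=BoundaryConditions(),
                     mean_inlet_speed=mean_speed or max(np.hypot(*u), 1e-3))


class TestForceModel:
    def test_derived_particle_quantities(self):
        p = ParticleProperties()
        assert p.mass == pytest.approx(1050 * math.pi * (14e-6) ** 3 / 6, rel=1e-12)
        assert p.projected_area == pytest.approx(math.pi * (14e-6) ** 2 / 4, rel=1e-12)

    def test_particle_reynolds_reference(self):
        re = particle_reynolds(FLUID, 3.66e-6, 14e-6)
        assert re == pytest.approx(3.5e-5, rel=0.02)
        assert particle_reynolds(FLUID, 0.0, 14e-6) == 0.0
        with pytest.raises(ValueError):
            particle_reynolds(FLUID, -1.0, 14e-6)

    def test_drag_coefficient_values(self):
        assert drag_coefficient(1.0) == pytest.approx(27.6)
        assert drag_coefficient(0.1) == pytest.approx(247.4, rel=1e-3)
        # Stokes limit: C_d * Re_p -> 24
        for re in (1e-4, 1e-6, 1e-8):
            assert drag_coefficient(re) * re == pytest.approx(24.0, rel=1e-2)
        with pytest.raises(ValueError):
            drag_coefficient(0.0)
        with pytest.raises(ValueError):
            drag_coefficient(-1.0)

    def test_drag_force_stokes_regime(self):
        p = ParticleProperties()
        vs = np.array([1e-4, 0.0])
        f = drag_force(p, FLUID, vs)
        stokes = 3 * math.pi * FLUID.dynamic_viscosity * p.diameter * 1e-4
        assert np.linalg.norm(f) == pytest.approx(stokes, rel=5e-3)
        assert np.linalg.norm(f) == pytest.approx(1.93e-11, rel=5e-3)
        # force is parallel to the slip velocity
        assert f[1] == 0.0 and f[0] > 0
        # doubling the slip doubles the force up to the finite-Re correction
        f2 = drag_force(p, FLUID, 2 * vs)
        assert np.linalg.norm(f2) == pytest.approx(2 * np.linalg.norm(f), rel=2e-3)

    def test_drag_force_zero_slip_and_stokes_only(self):
        p = ParticleProperties()
        assert np.all(drag_force(p, FLUID, np.zeros(2)) == 0.0)
        vs = np.array([0.0, 2e-4])
        exact = 3 * math.pi * FLUID.dynamic_viscosity * p.diameter * 2e-4
        f = drag_force(p, FLUID, vs, schiller_naumann=False)
        assert np.linalg.norm(f) == pytest.approx(exact, rel=1e-12)

    def test_gravity_force(self):
        p = ParticleProperties()
        g = np.array([0.0, -GRAVITY])
        f = gravity_force(p, g)
        assert np.linalg.norm(f) == pytest.approx(1.48e-11, rel=5e-3)
        assert np.all(gravity_force(p) == 0.0)  # out-of-plane default
        fb = gravity_force(p, g, fluid=FLUID, buoyancy=True)
        assert np.linalg.norm(fb) == pytest.approx(
            (1050 - 1000) * p.volume * GRAVITY, rel=1e-12)
        # buoyancy correction vanishes as the fluid density does
        thin = FluidProperties(1e-9, FLUID.dynamic_viscosity)
        np.testing.assert_allclose(gravity_force(p, g, thin, buoyancy=True),
                                   gravity_force(p, g), rtol=1e-8)

    def test_relaxation_time(self):
        p = ParticleProperties()
        tau = particle_relaxation_time(p, FLUID)
        assert tau == pytest.approx(7.8e-6, rel=0.01)
        thick = FluidProperties(FLUID.density, 2 * FLUID.dynamic_viscosity)
        assert particle_relaxation_time(p, thick) == pytest.approx(tau / 2, rel=1e-12)
        # consistency with the settling oracle: tau g (1 - rho/rho_p) = v_settle
        v = tau * GRAVITY * (1 - FLUID.density / p.density)
        assert v == pytest.approx(stokes_settling_velocity(p, FLUID), rel=1e-12)


class TestIntegrator:
    def test_velocity_relaxation_matches_oracle(self, channel_mesh):
        """Released at rest in uniform flow, v(t) = u (1 - e^{-t/tau})."""
        u = np.array([0.01, 0.0])
        field = _uniform_field(channel_mesh, u)
        p = ParticleProperties()
        tau = particle_relaxation_time(p, FLUID)
        cfg = TrackingConfig(schiller_naumann=False)
        interp = FlowInterpolator(field)
        state = ParticleState(np.array([1e-3, 0.0]), np.zeros(2))
        dt = tau / 10
        for _ in range(30):
            state = step_particle(state, interp, dt, p, FLUID, cfg)
        expected = relaxation_oracle(0.0, u[0], tau, state.time)
        assert state.velocity[0] == pytest.approx(expected, rel=1e-3)
        assert abs(state.velocity[0] - expected) / u[0] < 1e-3

    def test_stationary_without_flow_or_gravity(self, channel_mesh):
        field = _uniform_field(channel_mesh, [0.0, 0.0], mean_speed=1e-3)
        p = ParticleProperties()
        state = ParticleState(np.array([2e-3, 1e-4]), np.zeros(2))
        state = step_particle(state, field, 1e-3, p, FLUID)
        np.testing.assert_allclose(state.position, [2e-3, 1e-4])
        np.testing.assert_allclose(state.velocity, 0.0)

    def test_settling_to_stokes_terminal_velocity(self, channel_mesh):
        field = _uniform_field(channel_mesh, [0.0, 0.0], mean_speed=1e-3)
        p = ParticleProperties()
        cfg = TrackingConfig(gravity_vector=(0.0, -GRAVITY), buoyancy=True)
        interp = FlowInterpolator(field)
        state = ParticleState(np.array([5e-3, 5e-4]), np.zeros(2))
        for _ in range(40):
            state = step_particle(state, interp, 2e-6, p, FLUID, cfg)
        v_exp = stokes_settling_velocity(p, FLUID)
        assert v_exp == pytest.approx(3.66e-6, rel=0.01)
        assert -state.velocity[1] == pytest.approx(v_exp, rel=0.01)

    def test_halving_dt_reduces_error(self, channel_flow):
        """Trajectory error against a fine-step reference drops with dt."""
        p = ParticleProperties()
        cfg = TrackingConfig(gravity_vector=(0.0, -GRAVITY), buoyancy=True)
        interp = FlowInterpolator(channel_flow)

        def integrate(dt, t_end=0.08):
            state = ParticleState(np.array([5e-4, 3e-4]),
                                  interp.velocity(np.array([[5e-4, 3e-4]]))[0][0])
            while state.time < t_end - 1e-12 and state.status == "in_flow":
                state = step_particle(state, interp, dt, p, FLUID, cfg)
            return state.position

        # reference at dt/8
        ref = integrate(1e-3 / 8)
        e1 = np.linalg.norm(integrate(1e-3) - ref)
        e2 = np.linalg.norm(integrate(1e-3 / 2) - ref)
        assert e2 < e1 / 1.8

    def test_terminal_state_rejected(self, channel_flow):
        p = ParticleProperties()
        state = ParticleState(np.array([5e-4, 0.0]), np.zeros(2),
                              status="wall_contact")
        with pytest.raises(ValueError):
            step_particle(state, channel_flow, 1e-4, p, FLUID)

    def test_outlet_exit_detected(self, channel_flow, channel):
        p = ParticleProperties()
        interp = FlowInterpolator(channel_flow)
        state = ParticleState(np.array([channel.length - 1e-5, 0.0]),
                              np.array([0.05, 0.0]))
        state = step_particle(state, interp, 5e-4, p, FLUID)
        assert state.status == "exited_outlet_1"


class TestEnsemble:
    def test_census_conservation(self, bif90_ensemble):
        assert sum(bif90_ensemble.census.values()) == bif90_ensemble.n

    def test_max_particle_reynolds_below_one(self, bif90_ensemble):
        assert 0 < bif90_ensemble.global_max_particle_re < 1.0

    def test_majority_exits_split_by_symmetry(self, bif90_ensemble):
        c = bif90_ensemble.census
        n_out = c["exited_outlet_1"] + c["exited_outlet_2"]
        assert n_out > 0.9 * bif90_ensemble.n
        assert abs(c["exited_outlet_1"] - c["exited_outlet_2"]) < 0.1 * n_out

    def test_deterministic_given_seed(self, bif90_flow, bif90, particle):
        spec = SeedingSpec(n=150, rng_seed=11)
        cfg = TrackingConfig(rng_seed=11)
        runs = []
        for _ in range(2):
            seeds = seed_inlet(spec, bif90)
            runs.append(track_particles(seeds, bif90_flow, particle, FLUID, cfg,
                                        watch_centre=bif90.apex,
                                        watch_radius=7e-5))
        assert runs[0].census == runs[1].census
        np.testing.assert_array_equal(runs[0].statuses, runs[1].statuses)
        np.testing.assert_array_equal(runs[0].min_watch_distance,
                                      runs[1].min_watch_distance)
        np.testing.assert_array_equal(runs[0].residence_times,
                                      runs[1].residence_times)

    def test_seeds_outside_domain_rejected(self, bif90_flow, particle):
        with pytest.raises(ValueError):
            track_particles(np.array([[50e-3, 0.0]]), bif90_flow, particle, FLUID)

    def test_centreline_particle_approaches_carina(self, bif90_flow, bif90, particle):
        """The axis streamline terminates at the stagnation point."""
        seeds = seed_inlet(SeedingSpec(n=1, distribution="centreline"), bif90)
        cfg = TrackingConfig(max_time=10.0)
        ens = track_particles(seeds, bif90_flow, particle, FLUID, cfg,
                              watch_centre=bif90.apex,
                              watch_radius=5 * particle.diameter)
        assert ens.min_watch_distance[0] < 5 * particle.diameter
        assert ens.residence_times[0] > 0

    def test_stored_trajectory_time_ordered(self, bif90_flow, bif90, particle):
        seeds = seed_inlet(SeedingSpec(n=3, rng_seed=2), bif90)
        cfg = TrackingConfig(store_trajectories=(0, 2))
        ens = track_particles(seeds, bif90_flow, particle, FLUID, cfg)
        assert set(ens.trajectories) == {0, 2}
        for arr in ens.trajectories.values():
            assert np.all(np.diff(arr[:, 0]) > 0)


class TestSegmentDisc:
    def test_full_chord_through_centre(self):
        t = segment_time_in_disc(np.array([[-2.0, 0.0]]), np.array([[2.0, 0.0]]),
                                 4.0, np.zeros(2), 1.0)
        assert t[0] == pytest.approx(2.0, rel=1e-12)  # 2r at unit speed

    def test_miss_and_stationary(self):
        t = segment_time_in_disc(np.array([[-2.0, 3.0]]), np.array([[2.0, 3.0]]),
                                 4.0, np.zeros(2), 1.0)
        assert t[0] == 0.0
        t = segment_time_in_disc(np.array([[0.1, 0.0]]), np.array([[0.1, 0.0]]),
                                 5.0, np.zeros(2), 1.0)
        assert t[0] == 5.0
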