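"""Carina metrics: low-velocity area, residence times, fractions, sweeps."""

import numpy as np
import pytest

from carinaflow import (ApexWindow, CarinaRegion, NAMED_MEDIA,
                        SeedingSpec, ScenarioSpec, TrackingConfig,
                        build_straight_channel, carina_fraction,
                        generate_mesh, low_velocity_area,
                        mesh_convergence_study, mirror_node_map,
                        poiseuille_profile, residence_time, seed_inlet,
                        track_particles, viscosity_sweep)
from carinaflow.flow import BoundaryConditions, FlowField, P2Space
from carinaflow.metrics import angle_sweep, evaluate_scenario

FLUID = NAMED_MEDIA["non_conditioned"]
W = 2e-3


def _field_from_vertex_velocity(mesh, vel_fn, mean_speed):
    space = P2Space(mesh)
    vel = vel_fn(space.node_coords)
    return FlowField(mesh=mesh, space=space, velocity=vel,
                     pressure=np.zeros(space.n_vertices), residuals=[0.0],
                     converged=True, fluid=FLUID, bc=BoundaryConditions(),
                     mean_inlet_speed=mean_speed)


class TestLowVelocityArea:
    def test_uniform_flow_above_threshold_gives_zero(self, channel_mesh):
        f = _field_from_vertex_velocity(
            channel_mesh, lambda xy: np.tile([0.03, 0.0], (len(xy), 1)), 0.03)
        assert low_velocity_area(f, channel_mesh, 0.5) == 0.0

    def test_poiseuille_band_matches_closed_form(self):
        """Near-wall band area: w (1 - sqrt(1-f)) per unit length."""
        ch = build_straight_channel(10e-3, W)
        mesh = generate_mesh(ch, W / 15, wall_layers=3)
        vbar = 0.03

        def vel(xy):
            return np.column_stack([poiseuille_profile(W, vbar, xy[:, 1]),
                                    np.zeros(len(xy))])

        f = _field_from_vertex_velocity(mesh, vel, vbar)
        for frac in (0.01, 0.05, 0.2):
            area = low_velocity_area(f, mesh, frac, reference_speed=1.5 * vbar)
            exact = 10e-3 * W * (1.0 - np.sqrt(1.0 - frac))
            assert area == pytest.approx(exact, rel=0.06)
        # spot value of the closed form at f = 0.01: 0.005012 w per unit length
        assert 1 - np.sqrt(0.99) == pytest.approx(0.005012, rel=1e-3)

    def test_monotone_in_threshold(self, bif90_flow, bif90_mesh):
        areas = [low_velocity_area(bif90_flow, bif90_mesh, f)
                 for f in (0.005, 0.01, 0.05, 0.2, 0.8)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_window_restriction_and_errors(self, bif90_flow, bif90_mesh, bif90):
        win = ApexWindow(centre=bif90.apex, radius=0.4e-3)
        a_win = low_velocity_area(bif90_flow, bif90_mesh, 0.01, window=win)
        a_all = low_velocity_area(bif90_flow, bif90_mesh, 0.01)
        assert 0 < a_win < a_all
        far = ApexWindow(centre=np.array([1.0, 1.0]), radius=1e-4)
        with pytest.raises(ValueError):
            low_velocity_area(bif90_flow, bif90_mesh, 0.01, window=far)
        with pytest.raises(ValueError):
            low_velocity_area(bif90_flow, bif90_mesh, 1.5)

    def test_mirror_invariance(self, bif90_flow, bif90_mesh, bif90):
        idx = mirror_node_map(bif90_mesh)
        space = bif90_flow.space
        mirrored = bif90_flow.velocity.copy()
        mirrored[:space.n_vertices] = (bif90_flow.vertex_velocity[idx]
                                       * np.array([1.0, -1.0]))
        f2 = FlowField(mesh=bif90_mesh, space=space, velocity=mirrored,
                       pressure=bif90_flow.pressure, residuals=[0.0],
                       converged=True, fluid=FLUID, bc=bif90_flow.bc,
                       mean_inlet_speed=bif90_flow.mean_inlet_speed)
        win = ApexWindow(centre=bif90.apex, radius=0.4e-3)
        assert low_velocity_area(f2, bif90_mesh, 0.01, window=win) == \
            pytest.approx(low_velocity_area(bif90_flow, bif90_mesh, 0.01,
                                            window=win), rel=1e-12)


class TestResidenceTime:
    def test_never_entering(self):
        traj = np.column_stack([np.linspace(0, 1, 50),
                                np.linspace(-5, 5, 50), np.full(50, 3.0)])
        assert residence_time(traj, CarinaRegion(np.zeros(2), 1.0)) == 0.0

    def test_central_chord(self):
        s, r = 2.0, 0.5
        t = np.linspace(0, 2, 400)
        traj = np.column_stack([t, -2 + s * t, np.zeros_like(t)])
        got = residence_time(traj, CarinaRegion(np.zeros(2), r))
        assert got == pytest.approx(2 * r / s, rel=1e-9)

    def test_off_centre_chord_vs_brute_force(self):
        s, r, b = 1.3, 0.8, 0.3
        t = np.linspace(0, 4, 1000)
        traj = np.column_stack([t, -2.6 + s * t, np.full_like(t, b)])
        region = CarinaRegion(np.zeros(2), r)
        exact = 2 * np.sqrt(r ** 2 - b ** 2) / s
        assert residence_time(traj, region) == pytest.approx(exact, rel=5e-3)
        # brute-force oracle: dense resampling and inside-counting
        tf = np.linspace(0, 4, 400_000)
        inside = np.hypot(-2.6 + s * tf, b) <= r
        brute = inside.mean() * 4.0
        assert residence_time(traj, region) == pytest.approx(brute, rel=5e-3)

    def test_invalid_trajectories(self):
        with pytest.raises(ValueError):
            residence_time(np.empty((0, 3)), CarinaRegion(np.zeros(2), 1.0))
        bad = np.array([[0.0, 0, 0], [-1.0, 1, 1]])
        with pytest.raises(ValueError):
            residence_time(bad, CarinaRegion(np.zeros(2), 1.0))


class TestCarinaFraction:
    def test_far_ensemble_zero(self, bif90_ensemble, particle, bif90):
        tiny = CarinaRegion(bif90.apex, 1e-9)
        assert carina_fraction(bif90_ensemble, tiny) == 0.0

    def test_brute_force_recount_agrees(self, bif90_flow, bif90, particle):
        """Stored-trajectory recount is an independent oracle."""
        seeds = seed_inlet(SeedingSpec(n=60, rng_seed=4), bif90)
        cfg = TrackingConfig(store_trajectories=tuple(range(60)))
        ens = track_particles(seeds, bif90_flow, particle, FLUID, cfg,
                              watch_centre=bif90.apex, watch_radius=7e-5)
        region = CarinaRegion(bif90.apex, 2e-4)
        brute = 0
        for i in range(60):
            xy = ens.trajectories[i][:, 1:3]
            seg = np.diff(xy, axis=0)
            f0 = xy[:-1] - bif90.apex
            ln2 = np.maximum((seg ** 2).sum(1), 1e-300)
            tt = np.clip(-(f0 * seg).sum(1) / ln2, 0, 1)
            dmin = np.linalg.norm(f0 + tt[:, None] * seg, axis=1).min()
            brute += dmin <= region.radius
        assert carina_fraction(ens, region) == pytest.approx(brute / 60)

    def test_singleton_centreline_fraction_is_one(self, bif90_flow, bif90, particle):
        seeds = seed_inlet(SeedingSpec(n=1, distribution="centreline"), bif90)
        ens = track_particles(seeds, bif90_flow, particle, FLUID,
                              TrackingConfig(max_time=10.0),
                              watch_centre=bif90.apex, watch_radius=7e-5)
        assert carina_fraction(ens, CarinaRegion(bif90.apex, 7e-5)) == 1.0

    def test_wrong_centre_rejected(self, bif90_ensemble):
        with pytest.raises(ValueError):
            carina_fraction(bif90_ensemble,
                            CarinaRegion(np.array([0.0, 0.0]), 1e-4))


SMALL = ScenarioSpec(seeding=SeedingSpec(n=60, rng_seed=9),
                     target_cell_size=W / 10)


class TestSweeps:
    def test_single_angle_matches_direct_run(self):
        df = angle_sweep([90.0], SMALL)
        assert len(df) == 1
        direct = evaluate_scenario(SMALL)
        assert df.loc[0, "low_velocity_area"] == pytest.approx(
            direct.low_velocity_area, rel=1e-12)
        assert df.loc[0, "residence_mean"] == pytest.approx(
            direct.residence_mean, rel=1e-12)

    def test_identical_fluids_ratio_one(self):
        twin = [FLUID, NAMED_MEDIA["non_conditioned"]]
        # widen the carina region so the tiny ensemble has entrants
        spec = ScenarioSpec(seeding=SeedingSpec(n=60, rng_seed=9),
                            target_cell_size=W / 10, region_radius=5e-4)
        df = viscosity_sweep(twin, spec)
        assert df["residence_mean"].iloc[0] > 0
        assert df["residence_ratio"].iloc[-1] == pytest.approx(1.0, abs=1e-12)

    def test_viscosity_sweep_requires_two_fluids(self):
        with pytest.raises(ValueError):
            viscosity_sweep([FLUID], SMALL)

    def test_convergence_identical_sizes_zero_variation(self, bif90):
        df = mesh_convergence_study(bif90, [W / 10, W / 10], SMALL)
        assert df.attrs["max_velocity_deviation"] == 0.0
        assert df.attrs["residence_deviation"] == 0.0
        assert df.attrs["pass_5pct"]

    def test_convergence_rejects_increasing_sizes(self, bif90):
        with pytest.raises(ValueError):
            mesh_convergence_study(bif90, [W / 20, W / 10], SMALL)
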