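"""Shared fixtures: one straight-channel and one bifurcation solve per session."""

import pytest

from carinaflow import (BoundaryConditions, NAMED_MEDIA, ParticleProperties,
                        SeedingSpec, TrackingConfig, build_bifurcation,
                        build_straight_channel, generate_mesh, seed_inlet,
                        solve_steady_flow, track_particles)

CALIBRE = 2e-3


@pytest.fixture(scope="session")
def medium():
    return NAMED_MEDIA["non_conditioned"]


@pytest.fixture(scope="session")
def bc():
    return BoundaryConditions()


@pytest.fixture(scope="session")
def channel():
    return build_straight_channel(10e-3, CALIBRE)


@pytest.fixture(scope="session")
def channel_mesh(channel):
    return generate_mesh(channel, CALIBRE / 12)


@pytest.fixture(scope="session")
def channel_flow(channel_mesh, medium, bc):
    return solve_steady_flow(channel_mesh, medium, bc)


@pytest.fixture(scope="session")
def bif90():
    return build_bifurcation(90.0, CALIBRE, 10e-3, 10e-3)


@pytest.fixture(scope="session")
def bif90_mesh(bif90):
    return generate_mesh(bif90, CALIBRE / 12)


@pytest.fixture(scope="session")
def bif90_flow(bif90_mesh, medium, bc):
    return solve_steady_flow(bif90_mesh, medium, bc)


@pytest.fixture(scope="session")
def particle():
    return ParticleProperties()


@pytest.fixture(scope="session")
def bif90_ensemble(bif90_flow, bif90, particle, medium):
    """Small tracked ensemble through the 90-degree bifurcation."""
    seeds = seed_inlet(SeedingSpec(n=800, rng_seed=7), bif90)
    return track_particles(seeds, bif90_flow, particle, medium,
                           TrackingConfig(rng_seed=7),
                           watch_centre=bif90.apex,
                           watch_radius=5 * particle.diameter)
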