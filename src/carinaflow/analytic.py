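"""Inlet seedings and closed-form reference solutions.

Everything here is dependency-free of the solver and tracker, so these
functions double as independent oracles for their validation tests:
plane Poiseuille flow for the momentum solver, Stokes settling and the
exponential drag-relaxation solution for the particle integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .particles import GRAVITY, ParticleProperties
from .flow import FluidProperties

__all__ = [
    "SeedingSpec",
    "seed_inlet",
    "poiseuille_profile",
    "stokes_settling_velocity",
    "relaxation_oracle",
]


@dataclass(frozen=True)
class SeedingSpec:
    """Inlet seeding description.

    ``margin`` keeps seeds clear of the no-slip walls (default one
    particle radius, so the sphere fits inside the channel).
    """

    n: int = 20_000
    distribution: str = "uniform"     # uniform | flow_weighted | centreline | fixed_list
    rng_seed: int = 0
    margin: float = 7e-6
    fixed_positions: tuple = ()

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.distribution not in ("uniform", "flow_weighted", "centreline", "fixed_list"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


def seed_inlet(spec: SeedingSpec, geometry) -> np.ndarray:
    """Seed positions across the inlet cross-section of ``geometry``.

    Seeds are placed a small distance downstream of the inlet boundary
    (one tenth of a calibre) so that every particle starts strictly
    inside the fluid domain.  ``uniform`` spreads particles evenly over
    the admissible transverse band; ``flow_weighted`` draws from the
    parabolic flux profile; ``centreline`` puts every seed on the axis.
    Reproducible for a fixed ``rng_seed``.
    """
    w = geometry.calibre
    half = w / 2.0 - spec.margin
    if half <= 0:
        raise ValueError("seeding margin must be smaller than the half-width")
    inlet_x = _inlet_x(geometry) + 0.1 * w
    rng = np.random.default_rng(spec.rng_seed)
    if spec.distribution == "uniform":
        y = rng.uniform(-half, half, spec.n)
    elif spec.distribution == "flow_weighted":
        # rejection sampling against the parabolic flux profile
        y = np.empty(spec.n)
        got = 0
        while got < spec.n:
            cand = rng.uniform(-half, half, 2 * (spec.n - got))
            acc = rng.uniform(0, 1, len(cand)) < (1.0 - (2 * cand / w) ** 2)
            take = cand[acc][: spec.n - got]
            y[got: got + len(take)] = take
            got += len(take)
    elif spec.distribution == "centreline":
        y = np.zeros(spec.n)
    else:
        pts = np.asarray(spec.fixed_positions, dtype=float)
        if pts.shape != (spec.n, 2):
            raise ValueError("fixed_list requires n positions of shape (n, 2)")
        return pts
    return np.column_stack([np.full(spec.n, inlet_x), y])


def _inlet_x(geometry) -> float:
    for tag, poly in geometry.outline_segments():
        if tag == "inlet":
            return float(poly[0, 0])
    raise ValueError("geometry has no inlet segment")


def poiseuille_profile(width: float, mean_speed: float, transverse_coordinate):
    """Plane Poiseuille speed 1.5 vbar (1 - (2y/w)^2) at coordinate y."""
    y = np.asarray(transverse_coordinate, dtype=float)
    if np.any(np.abs(y) > width / 2.0 + 1e-15):
        raise ValueError("transverse coordinate outside the channel")
    out = 1.5 * mean_speed * (1.0 - (2.0 * y / width) ** 2)
    return float(out) if out.ndim == 0 else out


def stokes_settling_velocity(particle: ParticleProperties,
                             fluid: FluidProperties) -> float:
    """Terminal settling speed (rho_p - rho) g D_p^2 / (18 mu)."""
    dp = particle.diameter
    return (particle.density - fluid.density) * GRAVITY * dp * dp \
        / (18.0 * fluid.dynamic_viscosity)


def relaxation_oracle(initial_velocity, fluid_velocity, tau: float, t):
    """Closed-form linear-drag relaxation u + (v0 - u) exp(-t/tau)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    v0 = np.asarray(initial_velocity, dtype=float)
    u = np.asarray(fluid_velocity, dtype=float)
    tt = np.asarray(t, dtype=float)
    out = u + (v0 - u) * np.exp(-tt / tau)
    return float(out) if out.ndim == 0 else out
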