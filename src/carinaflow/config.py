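"""Run configuration with explicit units, and the end-to-end pipeline.

Configurations are YAML with unit-suffixed quantities ("2 mm",
"3 mL/min", "1.46 mPa.s"); values are converted to SI on parse and the
raw document is preserved verbatim, so serialising a config back out
reproduces the input unchanged.  The few parameters of the problem make
unit mistakes the dominant hazard, hence the mandatory suffixes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .analytic import SeedingSpec
from .flow import (BoundaryConditions, FluidProperties, NAMED_MEDIA,
                   SolverSettings)
from .metrics import ScenarioSpec, evaluate_scenario
from .particles import ParticleProperties, TrackingConfig
from . import io as cfio

__all__ = ["RunConfig", "run_pipeline", "parse_quantity", "format_quantity"]

#: unit -> SI factor, grouped by dimension for validation
_UNITS = {
    "length": {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6},
    "viscosity": {"Pa.s": 1.0, "mPa.s": 1e-3},
    "density": {"kg/m3": 1.0, "g/mL": 1000.0, "g/cm3": 1000.0},
    "flow_rate": {"m3/s": 1.0, "mL/min": 1e-6 / 60.0, "mL/s": 1e-6},
    "pressure": {"Pa": 1.0, "kPa": 1e3},
    "time": {"s": 1.0, "ms": 1e-3, "us": 1e-6},
}


def parse_quantity(value, dimension: str) -> float:
    """Parse "2 mm" (or a bare number for dimensionless use) to SI."""
    if isinstance(value, (int, float)):
        raise ValueError(
            f"quantity {value!r} needs an explicit unit ({dimension})")
    mag, _, unit = str(value).partition(" ")
    table = _UNITS[dimension]
    if unit not in table:
        raise ValueError(f"unknown {dimension} unit {unit!r} in {value!r}; "
                         f"accepted: {sorted(table)}")
    return float(mag) * table[unit]


def format_quantity(si_value: float, unit: str, dimension: str) -> str:
    """Format an SI value back into the given unit, e.g. (0.002,'mm')->'2 mm'."""
    factor = _UNITS[dimension][unit]
    return f"{si_value / factor:g} {unit}"


class RunConfig:
    """Parsed, validated run configuration.

    Construct with :meth:`from_yaml` (path or text) or
    :meth:`default`.  ``to_scenario()`` yields the in-memory
    :class:`~carinaflow.metrics.ScenarioSpec` driving the computation;
    ``raw`` keeps the original document for lossless round-tripping.
    """

    def __init__(self, raw: dict, text: Optional[str] = None):
        self.raw = raw
        self.text = text if text is not None else yaml.safe_dump(raw, sort_keys=False)
        self._scenario = self._build()  # validate eagerly

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        return cls(raw, text)

    @classmethod
    def default(cls) -> "RunConfig":
        return cls.from_yaml(DEFAULT_CONFIG)

    # -- parsing -----------------------------------------------------------
    def _build(self) -> ScenarioSpec:
        raw = self.raw
        g = raw.get("geometry", {})
        f = raw.get("fluid", {})
        pt = raw.get("particles", {})
        b = raw.get("bc", {})
        s = raw.get("solver", {})
        tr = raw.get("tracking", {})
        me = raw.get("metrics", {})

        calibre = parse_quantity(g.get("calibre", "2 mm"), "length")
        if "medium" in f:
            if f["medium"] not in NAMED_MEDIA:
                raise ValueError(f"unknown medium {f['medium']!r}; "
                                 f"choose from {sorted(NAMED_MEDIA)}")
            fluid = NAMED_MEDIA[f["medium"]]
        else:
            fluid = FluidProperties(
                density=parse_quantity(f.get("density", "1000 kg/m3"), "density"),
                dynamic_viscosity=parse_quantity(f.get("viscosity", "1.46 mPa.s"),
                                                 "viscosity"),
                label=f.get("label", ""))

        particle = ParticleProperties(
            diameter=parse_quantity(pt.get("diameter", "14 um"), "length"),
            density=parse_quantity(pt.get("density", "1.05 g/mL"), "density"))
        seeding = SeedingSpec(
            n=int(pt.get("n", 20000)),
            distribution=pt.get("distribution", "uniform"),
            rng_seed=int(tr.get("rng_seed", 0)),
            margin=parse_quantity(pt.get("margin", "7 um"), "length"))
        bc = BoundaryConditions(
            inlet_flow_rate=parse_quantity(b.get("flow_rate", "3 mL/min"),
                                           "flow_rate"),
            outlet_pressure=parse_quantity(b.get("outlet_pressure", "0 Pa"),
                                           "pressure"),
            inlet_profile=b.get("inlet_profile", "parabolic"))
        solver = SolverSettings(tolerance=float(s.get("tolerance", 1e-5)),
                                max_newton=int(s.get("max_newton", 30)))
        tracking = TrackingConfig(
            max_time=parse_quantity(tr.get("max_time", "30 s"), "time"),
            cfl=float(tr.get("cfl", 0.25)),
            rng_seed=int(tr.get("rng_seed", 0)),
            scheme=tr.get("scheme", "rk2"))

        cell = s.get("target_cell_size")
        spec = ScenarioSpec(
            angle_deg=float(g.get("angle_deg", 90.0)),
            calibre=calibre,
            parent_length=parse_quantity(g.get("parent_length", "10 mm"), "length"),
            branch_length=parse_quantity(g.get("branch_length", "10 mm"), "length"),
            carina_shape=g.get("carina_shape", "sharp"),
            blunt_radius=(parse_quantity(g["blunt_radius"], "length")
                          if "blunt_radius" in g else 0.0),
            target_cell_size=(parse_quantity(cell, "length") if cell else None),
            wall_layers=int(s.get("wall_layers", 2)),
            fluid=fluid, bc=bc, particle=particle, seeding=seeding,
            tracking=tracking, solver=solver,
            region_radius=(parse_quantity(me["region_radius"], "length")
                           if "region_radius" in me else None),
            threshold_fraction=float(me.get("threshold_fraction", 0.01)),
            window_radius=(parse_quantity(me["window_radius"], "length")
                           if "window_radius" in me else None),
        )
        return spec

    def to_scenario(self) -> ScenarioSpec:
        return self._scenario

    def to_yaml(self) -> str:
        return self.text

    def with_seed(self, seed: int) -> "RunConfig":
        raw = dict(self.raw)
        raw["tracking"] = dict(raw.get("tracking", {}), rng_seed=int(seed))
        return RunConfig(raw)

    def with_updates(self, **sections) -> "RunConfig":
        raw = dict(self.raw)
        for name, patch in sections.items():
            raw[name] = dict(raw.get(name, {}), **patch)
        return RunConfig(raw)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


DEFAULT_CONFIG = """\
geometry:
  angle_deg: 90
  calibre: 2 mm
  parent_length: 10 mm
  branch_length: 10 mm
  carina_shape: sharp
fluid:
  medium: non_conditioned
particles:
  diameter: 14 um
  density: 1.05 g/mL
  n: 20000
bc:
  flow_rate: 3 mL/min
  outlet_pressure: 0 Pa
  inlet_profile: parabolic
solver:
  tolerance: 1e-5
  wall_layers: 2
tracking:
  max_time: 30 s
  rng_seed: 0
metrics:
  threshold_fraction: 0.01
"""


def run_pipeline(config: RunConfig, outdir, seed: Optional[int] = None) -> dict:
    """Mesh -> solve -> track -> metrics, with all artifacts on disk.

    The run directory receives the config copy, mesh (VTK/MSH/npz),
    field (VTK/npz + residual history), trajectory census, metrics and
    a ``run.json`` carrying the config digest, seed and version so the
    run can be reproduced bit-identically.
    """
    from . import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = config.with_seed(seed)
    spec = config.to_scenario()
    (out / "config.yaml").write_text(config.to_yaml())

    stage = "mesh"
    try:
        metrics, mesh, flowfield, ensemble = evaluate_scenario(
            spec, return_objects=True)
        stage = "artifacts"
        cfio.write_vtk_mesh(mesh, out / "mesh.vtk")
        cfio.write_msh(mesh, out / "mesh.msh")
        cfio.save_mesh(mesh, out / "mesh.npz")
        (out / "geometry.json").write_text(mesh.geometry.to_json())
        cfio.write_vtk_flow(flowfield, out / "field.vtk")
        cfio.save_flowfield(flowfield, out / "field.npz")
        cfio.residuals_to_csv(flowfield, out / "residuals.csv")
        ensemble.to_frame().to_csv(out / "ensemble.csv", index=False)
        if ensemble.trajectories:
            cfio.trajectories_to_csv(ensemble.trajectories,
                                     out / "trajectories.csv")
            cfio.write_vtk_trajectories(ensemble.trajectories,
                                        out / "trajectories.vtk")
    except Exception as err:
        (out / "run.json").write_text(json.dumps(
            {"status": "failed", "stage": stage, "error": str(err),
             "config_digest": config.digest}, indent=1))
        raise

    summary = {
        "status": "ok",
        "version": __version__,
        "config_digest": config.digest,
        "rng_seed": spec.tracking.rng_seed,
        "metrics": _jsonify(metrics.to_dict()),
        "census": _jsonify(ensemble.census),
        "n_cells": mesh.num_cells,
        "final_residual": flowfield.residuals[-1],
    }
    (out / "metrics.json").write_text(json.dumps(summary["metrics"], indent=1))
    (out / "census.json").write_text(json.dumps(summary["census"], indent=1))
    (out / "run.json").write_text(json.dumps(summary, indent=1))
    return summary


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
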