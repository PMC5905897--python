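"""Run configuration and pipeline orchestration.

A run is described by a YAML file mapping directly onto
:class:`RunConfig`: where the inputs live (or a phantom spec to simulate
them), the reconstruction settings, the noise model, and a seed.  The
pipeline executes simulate → L-curve → reconstruct → evaluate and writes
every artifact plus a manifest so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as scio
from .errors import ConfigError
from .metrics import metrics_report
from .phantom import (
    Inclusion,
    NoiseSpec,
    PhantomSpec,
    add_noise,
    make_phantom,
    simulate_experiment,
)
from .recon import ReconSettings, calibrate_measurements, forward_measurements, reconstruct
from .solvers import SolverSettings
from .spectral import ChromophoreField, ExtinctionTable, default_hemoglobin_table

log = logging.getLogger("scdot")

__all__ = ["RunConfig", "parse_config", "run_pipeline"]

_SOLVER_KEYS = {
    "method", "epsilon_irls", "theta", "step_t", "max_inner_iter", "tol",
    "momentum", "backtracking",
}
_RECON_KEYS = {
    "lambda_reg", "max_outer_iter", "outer_tol", "c0", "data_transform",
    "robin_a", "trust_fraction", "lcurve_window",
}
_NOISE_KEYS = {"mode", "level", "bin_edges", "bin_levels", "seed"}
_PHANTOM_KEYS = {
    "radii", "edge_length", "inclusions", "n_sources", "n_detectors",
    "layout", "wavelengths",
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    output_dir: Path
    phantom: PhantomSpec | None = None
    simulation_edge_length: float | None = None
    measurement_path: Path | None = None
    extinction_path: Path | None = None
    recon: ReconSettings = dc_field(default_factory=ReconSettings)
    noise: NoiseSpec | None = None
    seed: int = 0
    calibrate: bool = True

    def extinction_table(self) -> ExtinctionTable:
        if self.extinction_path is not None:
            return ExtinctionTable.from_csv(self.extinction_path)
        return default_hemoglobin_table()


def _build(section: dict, allowed: set, context: str) -> dict:
    bad = set(section) - allowed
    if bad:
        raise ConfigError(f"unknown key(s) {sorted(bad)} in '{context}'")
    return section


def parse_config(path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Unknown keys raise :class:`ConfigError` naming the key; defaults for
    everything omitted are logged at INFO.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    known = {
        "output_dir", "phantom", "simulation_edge_length", "measurements",
        "extinction_table", "solver", "reconstruction", "noise", "seed",
        "calibrate",
    }
    bad = set(raw) - known
    if bad:
        raise ConfigError(f"unknown top-level key(s) {sorted(bad)}")
    if "output_dir" not in raw:
        raise ConfigError("missing required key 'output_dir'")

    phantom = None
    if "phantom" in raw:
        sect = _build(dict(raw["phantom"]), _PHANTOM_KEYS, "phantom")
        incs = tuple(Inclusion(**i) for i in sect.pop("inclusions", []))
        try:
            phantom = PhantomSpec(inclusions=incs, **sect)
        except Exception as exc:
            raise ConfigError(f"invalid phantom spec: {exc}")

    measurement_path = Path(raw["measurements"]) if "measurements" in raw else None
    if phantom is None and measurement_path is None:
        raise ConfigError("need either 'phantom' (simulate) or 'measurements'")
    if measurement_path is not None and not measurement_path.exists():
        raise ConfigError(f"measurement file {measurement_path} does not exist")

    extinction_path = None
    if "extinction_table" in raw:
        extinction_path = Path(raw["extinction_table"])
        if not extinction_path.exists():
            raise ConfigError(f"extinction table {extinction_path} does not exist")

    try:
        solver = SolverSettings(**_build(dict(raw.get("solver", {})), _SOLVER_KEYS, "solver"))
        recon_sect = _build(dict(raw.get("reconstruction", {})), _RECON_KEYS, "reconstruction")
        if "lcurve_window" in recon_sect and recon_sect["lcurve_window"] is not None:
            recon_sect["lcurve_window"] = tuple(recon_sect["lcurve_window"])
        recon = ReconSettings(solver=solver, **recon_sect)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(f"invalid solver/reconstruction settings: {exc}")

    noise = None
    if "noise" in raw and raw["noise"] is not None:
        sect = _build(dict(raw["noise"]), _NOISE_KEYS, "noise")
        try:
            noise = NoiseSpec(**sect)
        except Exception as exc:
            raise ConfigError(f"invalid noise spec: {exc}")

    cfg = RunConfig(
        output_dir=Path(raw["output_dir"]),
        phantom=phantom,
        simulation_edge_length=raw.get("simulation_edge_length"),
        measurement_path=measurement_path,
        extinction_path=extinction_path,
        recon=recon,
        noise=noise,
        seed=int(raw.get("seed", 0)),
        calibrate=bool(raw.get("calibrate", True)),
    )
    for name, default in (
        ("solver", solver.method), ("theta", solver.theta),
        ("epsilon_irls", solver.epsilon_irls), ("lambda", recon.lambda_reg),
        ("seed", cfg.seed),
    ):
        log.info("config %s = %s", name, default)
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns a manifest of what was produced.

    Artifacts written to ``output_dir``: the mesh, the (possibly noisy)
    measurement table, the L-curve scan (when lambda is "auto"), the
    per-node reconstruction, a metrics report against the ground truth
    (simulated runs only), and ``manifest.yaml``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = config.extinction_table()
    manifest: dict = {"seed": config.seed, "artifacts": {}}

    if config.phantom is None:
        raise ConfigError(
            "reconstruct-only runs need a phantom spec for mesh/optodes in "
            "this release"
        )

    spec = config.phantom
    mesh, truth, optodes = make_phantom(spec)
    scio.write_mesh(mesh, out / "mesh.node", out / "mesh.ele")
    scio.write_optodes(optodes, out / "optodes.csv", out / "links.csv")
    manifest["artifacts"]["mesh"] = ["mesh.node", "mesh.ele"]

    bg = spec.backgrounds[0]
    c0 = dict(config.recon.c0) or {"HbO2": bg.c1, "Hb": bg.c2}
    hom_field = ChromophoreField(
        {
            "HbO2": np.full(mesh.n_nodes, c0["HbO2"]),
            "Hb": np.full(mesh.n_nodes, c0["Hb"]),
        },
        truth.scatter_amplitude,
        truth.scatter_power,
    )

    if config.measurement_path is not None:
        measured = scio.read_measurements(config.measurement_path)
        log.info("loaded %d links from %s", measured.n_links, config.measurement_path)
    else:
        log.info("simulating measurements (edge=%s)", config.simulation_edge_length)
        measured = simulate_experiment(
            spec, table, edge_length=config.simulation_edge_length
        )
        if config.noise is not None:
            noise = replace(config.noise, seed=config.noise.seed or config.seed)
            measured = add_noise(measured, noise, optodes)
        if config.calibrate and config.simulation_edge_length is not None:
            hom_spec = replace(spec, inclusions=())
            hom_fine = simulate_experiment(
                hom_spec, table, edge_length=config.simulation_edge_length
            )
            hom_model = forward_measurements(
                mesh, hom_field, optodes, table, spec.wavelengths,
                robin_a=config.recon.robin_a,
            )
            measured = calibrate_measurements(measured, hom_fine, hom_model)
        scio.write_measurements(measured, out / "measurements.csv")
        manifest["artifacts"]["measurements"] = "measurements.csv"

    settings = replace(config.recon, c0=c0)
    result = reconstruct(
        measured, mesh, table, truth.scatter_amplitude, truth.scatter_power,
        optodes, settings,
    )
    delta = result.total_change()
    fields = {}
    for name in delta:
        fields[f"c_{name}"] = result.field.concentrations[name]
        fields[f"delta_{name}"] = delta[name]
    scio.write_node_field(fields, out / "reconstruction.csv")
    manifest["artifacts"]["reconstruction"] = "reconstruction.csv"
    manifest["lambda_used"] = float(result.lambda_used)
    manifest["outer_iterations"] = int(result.n_outer)
    manifest["residual_trace"] = [float(r) for r in result.residual_trace]

    truth_delta = {
        name: truth.concentrations[name] - c0[name] for name in delta
    }
    report = metrics_report(delta, truth_delta)
    manifest["metrics"] = {
        name: {k: float(v) for k, v in vals.items()}
        for name, vals in report.as_dict().items()
    }
    with open(out / "metrics.yaml", "w") as fh:
        yaml.safe_dump(manifest["metrics"], fh)
    manifest["artifacts"]["metrics"] = "metrics.yaml"

    manifest["settings"] = {
        "solver": settings.solver.method,
        "lambda_reg": settings.lambda_reg
        if not isinstance(settings.lambda_reg, str)
        else settings.lambda_reg,
        "data_transform": settings.data_transform,
        "max_outer_iter": settings.max_outer_iter,
        "noise": None if config.noise is None else asdict(config.noise),
        "simulation_edge_length": config.simulation_edge_length,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_clean_for_yaml(manifest), fh)
    return manifest


def _clean_for_yaml(obj):
    if isinstance(obj, dict):
        return {k: _clean_for_yaml(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean_for_yaml(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
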