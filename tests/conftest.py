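"""Shared fixtures: small meshes and the standard phantom study, built once
per session so the reconstruction-level tests stay fast."""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import scdot as sd
from scdot.recon import forward_measurements

hyp_settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
hyp_settings.load_profile("ci")

BACKGROUND = {"HbO2": 0.0548, "Hb": 0.0354}
INCLUSION_CENTER = np.array([10.0, 0.0])
INCLUSION_RADIUS = 4.0
DELTA_C1 = 0.005
SIM_EDGE = 1.4  # simulation mesh finer than the 2.5 mm reconstruction mesh


@pytest.fixture(scope="session")
def coarse_disk():
    """Tiny disk mesh for Jacobian finite-difference checks."""
    return sd.build_disk_mesh(10.0, 3.0)


@pytest.fixture(scope="session")
def extinction_table():
    return sd.default_hemoglobin_table()


@pytest.fixture(scope="session")
def standard_phantom(extinction_table):
    """The standard study: 25 mm disk, ring array, one 4 mm HbO2 inclusion.

    Simulated on a finer mesh than reconstruction uses (inverse-crime
    control) and calibrated against the homogeneous reference, mirroring the
    phantom-imaging workflow.  Returns a dict with everything the
    reconstruction tests need.
    """
    spec = sd.standard_phantom_spec()
    mesh, truth, optodes = sd.make_phantom(spec)
    het_fine = sd.simulate_experiment(spec, extinction_table, edge_length=SIM_EDGE)
    hom_fine = sd.simulate_experiment(
        replace(spec, inclusions=()), extinction_table, edge_length=SIM_EDGE
    )
    hom_field = sd.ChromophoreField(
        {name: np.full(mesh.n_nodes, val) for name, val in BACKGROUND.items()},
        truth.scatter_amplitude,
        truth.scatter_power,
    )
    hom_model = forward_measurements(
        mesh, hom_field, optodes, extinction_table, spec.wavelengths
    )
    calibrated = sd.calibrate_measurements(het_fine, hom_fine, hom_model)
    truth_delta = {
        name: truth.concentrations[name] - BACKGROUND[name] for name in BACKGROUND
    }
    return {
        "spec": spec,
        "mesh": mesh,
        "truth": truth,
        "truth_delta": truth_delta,
        "optodes": optodes,
        "het_fine": het_fine,
        "hom_fine": hom_fine,
        "hom_model": hom_model,
        "calibrated": calibrated,
        "table": extinction_table,
    }


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def reconstruct_standard(study, method, measured=None, lam="auto", max_outer=10,
                         **kwargs):
    """Run the study-protocol reconstruction (log data, windowed auto-lambda)."""
    settings = sd.ReconSettings(
        solver=sd.SolverSettings(method=method),
        lambda_reg=lam,
        c0=dict(BACKGROUND),
        max_outer_iter=max_outer,
        data_transform="log",
        lcurve_window=(1e-3, 1.0),
        **kwargs,
    )
    return sd.reconstruct(
        measured if measured is not None else study["calibrated"],
        study["mesh"],
        study["table"],
        study["truth"].scatter_amplitude,
        study["truth"].scatter_power,
        study["optodes"],
        settings,
    )
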