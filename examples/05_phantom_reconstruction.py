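"""Full pipeline on the standard phantom: simulate, calibrate, reconstruct.

A 25 mm disk with gray-matter background optics carries one 4 mm inclusion
with +5 uM oxyhemoglobin.  Data are simulated on a finer mesh than the
reconstruction uses (no inverse crime) and calibrated against the
homogeneous reference.  FISTA with the L-curve lambda recovers the
activation; runs in ~20 s.
"""

from dataclasses import replace

import numpy as np

import scdot as sd
from scdot.recon import forward_measurements

background = {"HbO2": 0.0548, "Hb": 0.0354}
spec = sd.standard_phantom_spec()
table = sd.default_hemoglobin_table()
mesh, truth, optodes = sd.make_phantom(spec)
print(f"reconstruction mesh: {mesh.n_nodes} nodes; links: {optodes.n_links} x 2 wavelengths")

het = sd.simulate_experiment(spec, table, edge_length=1.4)  # finer mesh
hom = sd.simulate_experiment(replace(spec, inclusions=()), table, edge_length=1.4)
hom_field = sd.ChromophoreField(
    {k: np.full(mesh.n_nodes, v) for k, v in background.items()},
    truth.scatter_amplitude, truth.scatter_power,
)
hom_model = forward_measurements(mesh, hom_field, optodes, table, spec.wavelengths)
measured = sd.calibrate_measurements(het, hom, hom_model)

settings = sd.ReconSettings(
    solver=sd.SolverSettings(method="fista"),
    lambda_reg="auto",            # L-curve corner on the first linearization
    c0=dict(background),
    data_transform="log",         # whitened misfit for proportional noise
    lcurve_window=(1e-3, 1.0),
    max_outer_iter=10,
)
result = sd.reconstruct(measured, mesh, table, truth.scatter_amplitude,
                        truth.scatter_power, optodes, settings)

delta = result.total_change()["HbO2"]
truth_delta = truth.concentrations["HbO2"] - background["HbO2"]
report = sd.metrics_report({"HbO2": delta}, {"HbO2": truth_delta})
peak = mesh.nodes[np.argmax(np.abs(delta))]

print(f"lambda chosen: {result.lambda_used:.3e}; outer iterations: {result.n_outer}")
print(f"recovered peak at ({peak[0]:.1f}, {peak[1]:.1f}) mm — truth centre (10.0, 0.0)")
print(f"AC  = {report.ac['HbO2']:.3f}   (1 = perfect region-mean contrast)")
print(f"PC  = {report.pc['HbO2']:.3f}   (correlation with the true map)")
print(f"PSNR= {report.psnr['HbO2']:.1f} dB")
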