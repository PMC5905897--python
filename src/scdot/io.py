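"""Plain-text readers and writers for meshes, optodes and measurements.

Formats:
* node file — one line per node: ``x y [z] boundary_flag region_label``;
* element file — one line per element, 1-based node indices;
* optode CSV — columns kind (source|detector), x, y, [z];
* link CSV — columns source_index, detector_index (1-based);
* measurement CSV — columns wavelength_nm, source_index, detector_index,
  amplitude (1-based indices).

Writers use round-trip-exact float formatting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError
from .mesh import Mesh, OptodeArray
from .recon import MeasurementSet

__all__ = [
    "write_mesh",
    "read_mesh",
    "write_optodes",
    "read_optodes",
    "write_measurements",
    "read_measurements",
    "write_node_field",
    "read_node_field",
]

_FMT = "%.17g"


def write_mesh(mesh: Mesh, node_path, element_path) -> None:
    coords = [_FMT % v for v in mesh.nodes.ravel()]
    ncol = mesh.dimension
    with open(node_path, "w") as fh:
        for i in range(mesh.n_nodes):
            xyz = " ".join(coords[i * ncol : (i + 1) * ncol])
            fh.write(f"{xyz} {int(mesh.boundary[i])} {int(mesh.regions[i])}\n")
    with open(element_path, "w") as fh:
        for el in mesh.elements + 1:  # 1-based on disk
            fh.write(" ".join(str(v) for v in el) + "\n")


def read_mesh(node_path, element_path) -> Mesh:
    raw = np.loadtxt(node_path, ndmin=2)
    if raw.shape[1] not in (4, 5):
        raise DimensionError("node file must have x y [z] boundary region columns")
    dim = raw.shape[1] - 2
    nodes = raw[:, :dim]
    boundary = raw[:, dim].astype(bool)
    regions = raw[:, dim + 1].astype(np.int64)
    elements = np.loadtxt(element_path, dtype=np.int64, ndmin=2) - 1
    return Mesh(nodes, elements, boundary, regions)


def write_optodes(optodes: OptodeArray, optode_path, link_path) -> None:
    rows = []
    for p in optodes.source_positions:
        rows.append(["source", *p])
    for p in optodes.detector_positions:
        rows.append(["detector", *p])
    dim = optodes.source_positions.shape[1]
    cols = ["kind", "x", "y"] + (["z"] if dim == 3 else [])
    pd.DataFrame(rows, columns=cols).to_csv(optode_path, index=False, float_format=_FMT)
    pd.DataFrame(
        optodes.link_table + 1, columns=["source_index", "detector_index"]
    ).to_csv(link_path, index=False)


def read_optodes(optode_path, link_path, musp_background: float = 1.0) -> OptodeArray:
    df = pd.read_csv(optode_path, float_precision="round_trip")
    dim = 3 if "z" in df.columns else 2
    cols = ["x", "y", "z"][:dim]
    src = df[df["kind"] == "source"][cols].to_numpy(float)
    det = df[df["kind"] == "detector"][cols].to_numpy(float)
    if not len(src) or not len(det):
        raise ParameterError("optode file must list both sources and detectors")
    links = pd.read_csv(link_path).to_numpy(np.int64) - 1
    radius = np.linalg.norm(src, axis=1)
    interior = src * (1.0 - (1.0 / musp_background) / radius)[:, None]
    return OptodeArray(src, det, links, interior)


def write_measurements(ms: MeasurementSet, path) -> None:
    rows = []
    for j, wl in enumerate(ms.wavelengths):
        for i, (s, d) in enumerate(ms.links):
            rows.append([wl, s + 1, d + 1, ms.amplitudes[i, j]])
    pd.DataFrame(
        rows, columns=["wavelength_nm", "source_index", "detector_index", "amplitude"]
    ).to_csv(path, index=False, float_format=_FMT)


def read_measurements(path) -> MeasurementSet:
    df = pd.read_csv(path, float_precision="round_trip")
    wavelengths = tuple(sorted(df["wavelength_nm"].unique()))
    first = df[df["wavelength_nm"] == wavelengths[0]]
    links = first[["source_index", "detector_index"]].to_numpy(np.int64) - 1
    amps = np.column_stack(
        [
            df[df["wavelength_nm"] == wl]["amplitude"].to_numpy(float)
            for wl in wavelengths
        ]
    )
    return MeasurementSet(wavelengths, links, amps)


def write_node_field(fields: dict, path) -> None:
    """Per-node CSV: node_index plus one column per named field."""
    n = len(next(iter(fields.values())))
    df = pd.DataFrame({"node_index": np.arange(1, n + 1)})
    for name, vals in fields.items():
        df[name] = np.asarray(vals, dtype=float)
    df.to_csv(path, index=False, float_format=_FMT)


def read_node_field(path) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    return {
        c: df[c].to_numpy(float) for c in df.columns if c != "node_index"
    }
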