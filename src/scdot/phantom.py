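"""Synthetic phantoms, simulated measurements, and measurement noise.

The generator emulates the bench-scale version of the studies this package
targets: a layered circular domain with tissue-like background optics
(defaults are the gray-matter head-tissue row: HbO2 0.0548 mM, Hb
0.0354 mM, Mie amplitude 0.5040, power 1.7757), small disk inclusions with
additive concentration changes (e.g. +-5 uM) or multiplicative contrast
(e.g. doubling), a dense ring of sources and detectors, and proportional
Gaussian measurement noise — either a flat percentage or binned by
source-detector distance as in high-density arrays (0.12/0.15/0.41/1.42%
for first through fourth nearest neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np

from .errors import ParameterError
from .mesh import OptodeArray, build_disk_mesh, build_layered_disk_mesh, position_optodes
from .recon import MeasurementSet, forward_measurements
from .spectral import ChromophoreField, ExtinctionTable, mie_musp

__all__ = [
    "Inclusion",
    "RegionBackground",
    "PhantomSpec",
    "NoiseSpec",
    "make_phantom",
    "simulate_experiment",
    "add_noise",
    "standard_phantom_spec",
]

# Head-tissue optical rows (concentrations mM, Mie amplitude/power):
TISSUE_BACKGROUNDS = {
    "scalp": dict(c1=0.0575, c2=0.0313, amplitude=0.53, power=1.1599),
    "skull": dict(c1=0.0438, c2=0.0209, amplitude=0.7258, power=0.8987),
    "csf": dict(c1=0.011, c2=0.0083, amplitude=0.3, power=0.9e-6),
    "gray_matter": dict(c1=0.0548, c2=0.0354, amplitude=0.5040, power=1.7757),
    "white_matter": dict(c1=0.0683, c2=0.0273, amplitude=0.8176, power=1.3048),
}


@dataclass
class RegionBackground:
    """Homogeneous background optics for one mesh region."""

    c1: float
    c2: float
    amplitude: float
    power: float

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ParameterError("background concentrations must be positive")
        if self.amplitude <= 0:
            raise ParameterError("scattering amplitude must be positive")


@dataclass
class Inclusion:
    """A disk-shaped perturbation of the chromophore field.

    Additive mode adds (delta_c1, delta_c2) inside the disk; multiplicative
    mode multiplies the background by those factors instead (supporting
    "double the background" style activations).
    """

    center: tuple
    radius: float
    delta_c1: float = 0.0
    delta_c2: float = 0.0
    multiplicative: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("inclusion radius must be positive")


@dataclass
class PhantomSpec:
    """Geometry, background, inclusions, optodes and wavelengths."""

    radii: tuple = (25.0,)  # disk (one entry) or layered annuli, outermost first
    edge_length: float = 2.5
    backgrounds: tuple | None = None  # one RegionBackground per region
    inclusions: tuple = ()
    n_sources: int = 16
    n_detectors: int = 16
    layout: str = "ring"
    wavelengths: tuple = (750.0, 850.0)

    def __post_init__(self) -> None:
        self.radii = tuple(float(r) for r in self.radii)
        if self.backgrounds is None:
            gm = RegionBackground(**TISSUE_BACKGROUNDS["gray_matter"])
            self.backgrounds = tuple([gm] * len(self.radii))
        if len(self.backgrounds) != len(self.radii):
            raise ParameterError("need one background per region")
        for inc in self.inclusions:
            r = np.linalg.norm(np.asarray(inc.center, float))
            if r + inc.radius > self.radii[0] + 1e-9:
                raise ParameterError(
                    f"inclusion at {inc.center} extends outside the geometry"
                )


def standard_phantom_spec(**overrides) -> PhantomSpec:
    """The standard 2D test phantom: 25 mm disk, 16 sources / 16 detectors
    on a ring, one 4 mm inclusion at (10, 0) with +0.005 mM HbO2."""
    spec = PhantomSpec(
        inclusions=(Inclusion(center=(10.0, 0.0), radius=4.0, delta_c1=0.005),)
    )
    return replace(spec, **overrides) if overrides else spec


def make_phantom(spec: PhantomSpec, edge_length: float | None = None):
    """Build (mesh, ground-truth chromophore field, optode array).

    ``edge_length`` overrides the phantom's mesh resolution — used to simulate
    data on a finer mesh than reconstruction, avoiding the inverse crime.
    """
    h = spec.edge_length if edge_length is None else float(edge_length)
    if len(spec.radii) == 1:
        mesh = build_disk_mesh(spec.radii[0], h)
    else:
        mesh = build_layered_disk_mesh(list(spec.radii), h)

    c1 = np.empty(mesh.n_nodes)
    c2 = np.empty(mesh.n_nodes)
    amp = np.empty(mesh.n_nodes)
    pow_ = np.empty(mesh.n_nodes)
    for label, bg in enumerate(spec.backgrounds):
        m = mesh.regions == label
        c1[m], c2[m] = bg.c1, bg.c2
        amp[m], pow_[m] = bg.amplitude, bg.power

    for inc in spec.inclusions:
        center = np.asarray(inc.center, dtype=float)
        inside = np.linalg.norm(mesh.nodes - center, axis=1) <= inc.radius + 1e-12
        if inc.multiplicative:
            c1[inside] *= inc.delta_c1 if inc.delta_c1 else 1.0
            c2[inside] *= inc.delta_c2 if inc.delta_c2 else 1.0
        else:
            c1[inside] += inc.delta_c1
            c2[inside] += inc.delta_c2

    truth = ChromophoreField({"HbO2": c1, "Hb": c2}, amp, pow_)
    musp750 = float(np.mean(mie_musp(amp, pow_, spec.wavelengths[0])))
    optodes = position_optodes(
        mesh, spec.n_sources, spec.n_detectors, spec.layout,
        musp_background=musp750,
    )
    return mesh, truth, optodes


def simulate_experiment(
    spec: PhantomSpec,
    table: ExtinctionTable,
    edge_length: float | None = None,
    robin_a: float | None = None,
) -> MeasurementSet:
    """Noise-free multispectral boundary data for a phantom.

    Pass a smaller ``edge_length`` than the reconstruction mesh uses to
    generate data on a finer discretization (inverse-crime control); the
    optode geometry is identical because optodes sit at exact analytic
    positions on the circle.
    """
    mesh, truth, optodes = make_phantom(spec, edge_length=edge_length)
    ms = forward_measurements(
        mesh, truth, optodes, table, spec.wavelengths, robin_a=robin_a
    )
    return ms


@dataclass
class NoiseSpec:
    """Proportional Gaussian measurement noise.

    ``flat`` mode multiplies every amplitude by (1 + level * z); the
    distance-binned mode chooses the level from the source-detector
    separation, with default bins splitting at the midpoints between the
    nominal nearest-neighbour distances (13/30/40/48 mm) and the in-vivo
    noise ladder 0.12/0.15/0.41/1.42%.
    """

    mode: str = "flat"
    level: float = 0.01
    bin_edges: tuple = (0.0, 21.5, 35.0, 44.0, np.inf)
    bin_levels: tuple = (0.0012, 0.0015, 0.0041, 0.0142)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("flat", "distance_binned"):
            raise ParameterError("noise mode must be 'flat' or 'distance_binned'")
        if self.level < 0 or any(l < 0 for l in self.bin_levels):
            raise ParameterError("noise levels must be >= 0")
        if any(b <= a for a, b in zip(self.bin_edges, self.bin_edges[1:])):
            raise ParameterError("bin edges must be increasing")
        if len(self.bin_levels) != len(self.bin_edges) - 1:
            raise ParameterError("need one level per bin")


def add_noise(
    measurements: MeasurementSet,
    noise: NoiseSpec,
    optodes: OptodeArray | None = None,
) -> MeasurementSet:
    """Corrupt amplitudes with independent proportional Gaussian noise.

    The distance-binned mode needs the optode array to compute per-link
    source-detector separations; every link must fall inside a bin.
    Amplitudes driven non-positive are clipped to a small positive floor
    with a warning.
    """
    rng = np.random.default_rng(noise.seed)
    amps = measurements.amplitudes
    if noise.mode == "flat":
        level = np.full(measurements.n_links, noise.level)
    else:
        if optodes is None:
            raise ParameterError("distance-binned noise requires the optode array")
        dist = optodes.link_distances()
        idx = np.searchsorted(noise.bin_edges, dist, side="right") - 1
        if np.any(idx < 0) or np.any(idx >= len(noise.bin_levels)):
            raise ParameterError("a link distance falls outside all noise bins")
        level = np.asarray(noise.bin_levels, float)[idx]
    z = rng.standard_normal(amps.shape)
    noisy = amps * (1.0 + level[:, None] * z)
    floor = 1e-6 * amps
    if np.any(noisy <= 0):
        warnings.warn("noise drove amplitudes non-positive; clipping", stacklevel=2)
        noisy = np.maximum(noisy, floor)
    meta = {"mode": noise.mode, "level": noise.level, "seed": noise.seed}
    return MeasurementSet(measurements.wavelengths, measurements.links, noisy, meta)
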