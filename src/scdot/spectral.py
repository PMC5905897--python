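"""Spectral coupling: Beer's law, Mie scattering, and the spectral Jacobian.

Chromophore concentrations (oxy- and deoxyhemoglobin, mM) determine the
absorption coefficient at each wavelength through Beer's law,

    mua(lambda) = sum_c  epsilon[c, lambda] * conc[c],

while the reduced scattering follows the Mie-type power law
``musp = A * (lambda/1000 nm)^-b`` with the wavelength expressed in
micrometres.  The spectral sensitivity matrix stacks the per-wavelength
absorption Jacobians, scaled by the extinction coefficients, into the block
matrix that relates boundary-data changes directly to concentration changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DimensionError, NumericalError, ParameterError
from .fem import DiffusionSolver, OpticalField, element_gradients, _triple_product_pattern, _triple_scale
from .mesh import Mesh, OptodeArray, interpolation_weights

__all__ = [
    "ExtinctionTable",
    "ChromophoreField",
    "SpectralJacobian",
    "default_hemoglobin_table",
    "generic_dye_table",
    "mie_musp",
    "beer_law_mua",
    "invert_beer_law",
    "wavelength_jacobian",
    "spectral_jacobian",
]

# Compiled hemoglobin extinction coefficients (base-e, mm^-1 mM^-1) at the two
# standard near-infrared imaging wavelengths, as tabulated in the functional
# neuroimaging literature.
_HEMOGLOBIN_EPSILON = {
    ("HbO2", 750.0): 0.1193,
    ("HbO2", 850.0): 0.2437,
    ("Hb", 750.0): 0.3236,
    ("Hb", 850.0): 0.1591,
}


@dataclass
class ExtinctionTable:
    """Per-chromophore, per-wavelength extinction coefficients.

    ``epsilon`` has shape (n_chromophores, n_wavelengths), units mm^-1 mM^-1.
    """

    wavelengths: tuple
    chromophores: tuple
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        self.chromophores = tuple(self.chromophores)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (len(self.chromophores), len(self.wavelengths)):
            raise DimensionError("epsilon must be (n_chromophores, n_wavelengths)")
        if np.any(self.epsilon < 0):
            raise ParameterError("extinction coefficients must be non-negative")

    @property
    def n_chromophores(self) -> int:
        return len(self.chromophores)

    def _wl_index(self, wavelength: float) -> int:
        try:
            return self.wavelengths.index(float(wavelength))
        except ValueError:
            raise KeyError(
                f"wavelength {wavelength} nm not in table {self.wavelengths}"
            ) from None

    def value(self, chromophore: str, wavelength: float) -> float:
        return float(
            self.epsilon[self.chromophores.index(chromophore), self._wl_index(wavelength)]
        )

    def matrix(self, wavelengths=None) -> np.ndarray:
        """The Beer's-law matrix: rows are wavelengths, columns chromophores."""
        wls = self.wavelengths if wavelengths is None else wavelengths
        idx = [self._wl_index(w) for w in wls]
        return self.epsilon[:, idx].T

    def condition_number(self, wavelengths=None) -> float:
        return float(np.linalg.cond(self.matrix(wavelengths)))

    # -- text round trip --------------------------------------------------
    def to_csv(self, path) -> None:
        rows = [
            {"wavelength_nm": w, "chromophore": c, "epsilon_mm_per_mM": self.epsilon[i, j]}
            for i, c in enumerate(self.chromophores)
            for j, w in enumerate(self.wavelengths)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        df = pd.read_csv(path)
        chroms = tuple(dict.fromkeys(df["chromophore"]))
        wls = tuple(dict.fromkeys(df["wavelength_nm"].astype(float)))
        eps = np.zeros((len(chroms), len(wls)))
        for _, row in df.iterrows():
            eps[chroms.index(row["chromophore"]), wls.index(float(row["wavelength_nm"]))] = row[
                "epsilon_mm_per_mM"
            ]
        return cls(wls, chroms, eps)


def default_hemoglobin_table(wavelengths=(750.0, 850.0)) -> ExtinctionTable:
    """The documented default HbO2/Hb extinction table (mm^-1 mM^-1)."""
    chroms = ("HbO2", "Hb")
    eps = np.array(
        [[_HEMOGLOBIN_EPSILON[(c, float(w))] for w in wavelengths] for c in chroms]
    )
    return ExtinctionTable(wavelengths, chroms, eps)


def generic_dye_table(mua_by_wavelength: dict) -> ExtinctionTable:
    """Single-chromophore table for dye phantoms: the dye has unit
    concentration in the bulk, so its extinction equals the measured bulk
    absorption coefficient at each wavelength."""
    wls = tuple(float(w) for w in mua_by_wavelength)
    eps = np.array([[float(mua_by_wavelength[w]) for w in mua_by_wavelength]])
    return ExtinctionTable(wls, ("dye",), eps)


@dataclass
class ChromophoreField:
    """Per-node chromophore concentrations plus the (fixed) scatter prior.

    ``concentrations`` maps chromophore name to a per-node array (mM).
    Scattering amplitude and power may be scalars or per-node arrays; they
    parameterize the Mie power law and are never updated by reconstruction.
    """

    concentrations: dict
    scatter_amplitude: np.ndarray | float = 1.0
    scatter_power: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.concentrations = {
            k: np.atleast_1d(np.asarray(v, dtype=float))
            for k, v in self.concentrations.items()
        }
        n = {v.shape for v in self.concentrations.values()}
        if len(n) > 1:
            raise DimensionError("all concentration fields must share a shape")
        if np.any(np.atleast_1d(self.scatter_amplitude) <= 0):
            raise ParameterError("scattering amplitude must be positive")

    @property
    def names(self) -> tuple:
        return tuple(self.concentrations)

    @property
    def n_nodes(self) -> int:
        return next(iter(self.concentrations.values())).shape[0]

    def stacked(self, order=None) -> np.ndarray:
        order = order or self.names
        return np.concatenate([self.concentrations[c] for c in order])

    def copy(self) -> "ChromophoreField":
        return ChromophoreField(
            {k: v.copy() for k, v in self.concentrations.items()},
            np.copy(self.scatter_amplitude),
            np.copy(self.scatter_power),
        )

    def musp(self, wavelength: float) -> np.ndarray:
        return mie_musp(self.scatter_amplitude, self.scatter_power, wavelength)


def mie_musp(amplitude, power, wavelength: float):
    """Reduced scattering from the Mie power law, wavelength in nm.

    musp = amplitude * (wavelength / 1000)^(-power), i.e. the wavelength is
    expressed in micrometres; this convention reproduces the standard
    head-tissue scattering values from their amplitude/power parameters.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude <= 0):
        raise ParameterError("scattering amplitude must be positive")
    if wavelength <= 0:
        raise ParameterError("wavelength must be positive")
    return amplitude * (wavelength / 1000.0) ** (-np.asarray(power, dtype=float))


def beer_law_mua(table: ExtinctionTable, field: ChromophoreField, wavelength: float):
    """Absorption at one wavelength from chromophore concentrations."""
    j = table._wl_index(wavelength)
    mua = np.zeros(field.n_nodes)
    for name in field.names:
        mua = mua + table.value(name, wavelength) * field.concentrations[name]
    return mua


def invert_beer_law(table: ExtinctionTable, mua_by_wavelength: dict) -> dict:
    """Concentrations from per-wavelength absorption (exact 2x2-style solve).

    ``mua_by_wavelength`` maps wavelength to scalar or per-node mua.  The
    extinction submatrix for the given wavelengths must be square and
    well-conditioned.
    """
    wls = list(mua_by_wavelength)
    E = table.matrix(wls)  # (n_wl, n_chrom)
    if E.shape[0] != E.shape[1]:
        raise DimensionError("need as many wavelengths as chromophores")
    if np.linalg.cond(E) > 1e12:
        raise NumericalError("extinction submatrix is singular")
    rhs = np.vstack([np.atleast_1d(np.asarray(mua_by_wavelength[w], float)) for w in wls])
    c = np.linalg.solve(E, rhs)
    return {name: c[i] for i, name in enumerate(table.chromophores)}


@dataclass
class SpectralJacobian:
    """Block sensitivity matrix coupling wavelengths to chromophores.

    Row block i holds the measurements at wavelength i; column block j the
    nodes of chromophore j.  Block (i, j) is the per-wavelength absorption
    Jacobian scaled by the extinction coefficient of chromophore j at
    wavelength i.  The per-wavelength sub-Jacobians are retained.
    """

    sub_jacobians: list
    table: ExtinctionTable
    wavelengths: tuple

    def __post_init__(self) -> None:
        self.sub_jacobians = [np.asarray(J, dtype=float) for J in self.sub_jacobians]
        shapes = {J.shape for J in self.sub_jacobians}
        if len(shapes) != 1:
            raise DimensionError("per-wavelength Jacobians must share a shape")
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if len(self.wavelengths) != len(self.sub_jacobians):
            raise DimensionError("one sub-Jacobian per wavelength required")

    @property
    def n_measurements(self) -> int:
        return self.sub_jacobians[0].shape[0]

    @property
    def n_nodes(self) -> int:
        return self.sub_jacobians[0].shape[1]

    @property
    def shape(self) -> tuple:
        return (
            len(self.wavelengths) * self.n_measurements,
            self.table.n_chromophores * self.n_nodes,
        )

    def block(self, i: int, j: int) -> np.ndarray:
        eps = self.table.value(self.table.chromophores[j], self.wavelengths[i])
        return self.sub_jacobians[i] * eps

    @property
    def matrix(self) -> np.ndarray:
        return np.block(
            [
                [self.block(i, j) for j in range(self.table.n_chromophores)]
                for i in range(len(self.wavelengths))
            ]
        )


def spectral_jacobian(sub_jacobians, table: ExtinctionTable, wavelengths) -> SpectralJacobian:
    """Assemble the block spectral Jacobian from per-wavelength sub-Jacobians."""
    for w in wavelengths:
        table._wl_index(w)  # raises KeyError if epsilon is missing
    return SpectralJacobian(list(sub_jacobians), table, tuple(wavelengths))


def wavelength_jacobian(
    mesh: Mesh,
    field: OpticalField,
    optodes: OptodeArray,
    solver: DiffusionSolver | None = None,
) -> np.ndarray:
    """Adjoint sensitivity of boundary amplitudes to nodal absorption.

    Entry (m, n) is the derivative of link m's amplitude with respect to mua
    at node n — the exact derivative of the discrete forward model, combining
    the absorption mass term with the absorption dependence of the diffusion
    coefficient (d kappa/d mua = -3 kappa^2).  Forward fields are computed per
    source and adjoint fields per detector from a single factorization.
    """
    if solver is None:
        solver = DiffusionSolver(mesh, field)
    links = optodes.link_table
    phi = solver.solve_sources(optodes.interior_source_points)  # (ns, nn)
    Wd = interpolation_weights(mesh, optodes.detector_positions)
    psi = solver.solve(Wd.T, check=False).T  # (nd, nn) adjoint fields
    return _assemble_absorption_jacobian(mesh, field, phi, psi, links)


def _assemble_absorption_jacobian(mesh, field, phi, psi, links):
    d = mesh.dimension
    elems = mesh.elements
    ne, nloc = mesh.n_elements, d + 1
    grads, vol = element_gradients(mesh)
    F = _triple_product_pattern(d)
    base = _triple_scale(d, vol)

    phi_e = phi[links[:, 0]][:, elems]  # (nl, ne, nloc)
    psi_e = psi[links[:, 1]][:, elems]

    # mass term: -psi^T (dM/dmua_n) phi, exact P1 triple-product integration
    mass = np.einsum("kij,mei,mej->mek", F, psi_e, phi_e, optimize=True)
    mass *= base[None, :, None]

    # diffusion term: dK/dmua_n = (dkappa/dmua) * V/(d+1) * G G^T per element
    GGT = np.einsum("ead,ebd->eab", grads, grads)
    stiff = np.einsum("eab,mea,meb->me", GGT, psi_e, phi_e, optimize=True)
    stiff = stiff * (vol / nloc)[None, :]
    kap2 = 3.0 * field.kappa[elems] ** 2  # (ne, nloc): -dkappa/dmua per node
    contrib = -mass + kap2[None, :, :] * stiff[:, :, None]

    # scatter element-local contributions into node columns
    nl = len(links)
    scatter = sp.coo_matrix(
        (np.ones(ne * nloc), (np.arange(ne * nloc), elems.ravel())),
        shape=(ne * nloc, mesh.n_nodes),
    ).tocsr()
    J = (scatter.T @ contrib.reshape(nl, -1).T).T
    return np.ascontiguousarray(J)
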