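"""P1 finite-element forward model for continuous-wave light transport.

Photon transport is modelled by the diffusion approximation

    -div( kappa grad Phi ) + mua Phi = q0,      kappa = 1/(3 (mua + musp)),

with a Robin (type III, index-mismatched) boundary condition
``Phi + 2 A kappa dPhi/dn = 0`` so that fluence leaves the tissue and does
not return.  The reflection parameter ``A`` is computed from the relative
refractive index by the usual diffuse-reflectance fit (A = 1 for a matched
boundary).  Assembly uses exact P1 integration for all terms, including the
third-order tensor ``\\int mua phi_i phi_j`` with nodally varying mua — this
makes the adjoint sensitivity matrix the exact derivative of the discrete
forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import DimensionError, NumericalError, ParameterError
from .mesh import Mesh, OptodeArray, interpolation_weights

__all__ = [
    "OpticalField",
    "robin_coefficient",
    "DiffusionSolver",
    "solve_diffusion",
    "boundary_measurements",
]

DEFAULT_REFRACTIVE_INDEX = 1.33


@dataclass
class OpticalField:
    """Nodal optical properties at one wavelength.

    mua, musp in mm^-1; kappa (mm) is derived, never stored.
    """

    mua: np.ndarray
    musp: np.ndarray
    wavelength: float = 0.0

    def __post_init__(self) -> None:
        self.mua = np.atleast_1d(np.asarray(self.mua, dtype=float))
        self.musp = np.atleast_1d(np.asarray(self.musp, dtype=float))
        if self.mua.shape != self.musp.shape:
            raise DimensionError("mua and musp must have the same shape")
        if np.any(self.mua <= 0) or np.any(self.musp <= 0):
            raise ParameterError("mua and musp must be strictly positive")

    @property
    def kappa(self) -> np.ndarray:
        return 1.0 / (3.0 * (self.mua + self.musp))


def robin_coefficient(refractive_index: float = DEFAULT_REFRACTIVE_INDEX) -> float:
    """Index-mismatch reflection parameter A for the Robin boundary term.

    Uses the Groenhuis/Keijzer polynomial fit for the internal diffuse
    reflection coefficient r_d; A = (1 + r_d)/(1 - r_d).  A = 1 recovers the
    index-matched boundary.
    """
    n = float(refractive_index)
    if n <= 0:
        raise ParameterError("refractive index must be positive")
    if n == 1.0:
        return 1.0
    rd = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + rd) / (1.0 - rd)


def element_gradients(mesh: Mesh):
    """Constant P1 basis gradients per element.

    Returns ``(grads, volumes)`` with grads of shape
    (n_elements, d+1, d): row k is the gradient of the barycentric basis
    function of local node k.
    """
    d = mesh.dimension
    p = mesh.nodes[mesh.elements]
    edges = np.swapaxes(p[:, 1:, :] - p[:, :1, :], 1, 2)  # columns p_k - p_0
    inv = np.linalg.inv(edges)  # row k-1 is grad(lambda_k), k = 1..d
    grads = np.empty((mesh.n_elements, d + 1, d))
    grads[:, 1:, :] = inv
    grads[:, 0, :] = -inv.sum(axis=1)
    vol = mesh.element_volumes()
    return grads, vol


# pattern multiplier for \int phi_k phi_i phi_j over a simplex:
# 6 when k=i=j, 2 when exactly two coincide, 1 when all distinct;
# the scale factor is d! V / (d+3)!.
def _triple_product_pattern(d: int) -> np.ndarray:
    n = d + 1
    F = np.ones((n, n, n))
    for k in range(n):
        for i in range(n):
            for j in range(n):
                m = (k == i) + (k == j) + (i == j)
                F[k, i, j] = 6.0 if m == 3 else (2.0 if m == 1 else 1.0)
    return F


def _triple_scale(d: int, vol: np.ndarray) -> np.ndarray:
    import math

    return math.factorial(d) * vol / math.factorial(d + 3)


class DiffusionSolver:
    """Assembled CW diffusion system for one optical field on one mesh.

    Caches the sparse LU factorization so that many point-source and adjoint
    solves at the same wavelength reuse a single assembly.
    """

    def __init__(
        self,
        mesh: Mesh,
        field: OpticalField,
        robin_a: float | None = None,
        refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
    ):
        if field.mua.shape != (mesh.n_nodes,):
            raise DimensionError("optical field must be defined on every mesh node")
        self.mesh = mesh
        self.field = field
        self.robin_a = robin_coefficient(refractive_index) if robin_a is None else float(robin_a)
        if self.robin_a <= 0:
            raise ParameterError("Robin coefficient A must be positive")
        self.system = self._assemble()
        try:
            self._lu = splu(self.system.tocsc())
        except RuntimeError as exc:  # pragma: no cover - singular assembly
            raise NumericalError(f"diffusion system factorization failed: {exc}")

    # -- assembly ---------------------------------------------------------
    def _assemble(self) -> sp.csr_matrix:
        mesh, field = self.mesh, self.field
        d = mesh.dimension
        ne, nloc = mesh.n_elements, d + 1
        grads, vol = element_gradients(mesh)
        kap = field.kappa
        kap_e = kap[mesh.elements].mean(axis=1)
        K_loc = (kap_e * vol)[:, None, None] * np.einsum(
            "ead,ebd->eab", grads, grads
        )
        # absorption mass term with nodal mua, exact P1 integration
        F = _triple_product_pattern(d)
        base = _triple_scale(d, vol)
        mua_e = field.mua[mesh.elements]  # (ne, nloc)
        M_loc = base[:, None, None] * np.einsum("kij,ek->eij", F, mua_e)
        A_loc = K_loc + M_loc
        rows = np.repeat(mesh.elements, nloc, axis=1).reshape(ne, nloc, nloc)
        cols = np.swapaxes(rows, 1, 2)
        A = sp.coo_matrix(
            (A_loc.ravel(), (rows.ravel(), cols.ravel())),
            shape=(mesh.n_nodes, mesh.n_nodes),
        ).tocsr()
        A = A + self._robin_matrix()
        return A

    def _robin_matrix(self) -> sp.csr_matrix:
        mesh = self.mesh
        facets = mesh.boundary_facets()
        d = mesh.dimension
        p = mesh.nodes[facets]
        if d == 2:
            size = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
            loc = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0
        else:
            size = 0.5 * np.linalg.norm(
                np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
            )
            loc = (np.ones((3, 3)) + np.eye(3)) / 12.0
        coef = 1.0 / (2.0 * self.robin_a)
        vals = coef * size[:, None, None] * loc[None, :, :]
        nloc = facets.shape[1]
        rows = np.repeat(facets, nloc, axis=1).reshape(len(facets), nloc, nloc)
        cols = np.swapaxes(rows, 1, 2)
        return sp.coo_matrix(
            (vals.ravel(), (rows.ravel(), cols.ravel())),
            shape=(mesh.n_nodes, mesh.n_nodes),
        ).tocsr()

    # -- solves -----------------------------------------------------------
    def solve(self, rhs: np.ndarray, check: bool = True) -> np.ndarray:
        """Solve the assembled system for one or many right-hand sides."""
        rhs = np.asarray(rhs, dtype=float)
        x = self._lu.solve(rhs)
        if check:
            res = np.linalg.norm(self.system @ x - rhs) / max(
                np.linalg.norm(rhs), 1e-300
            )
            if not np.isfinite(res) or res > 1e-10:
                raise NumericalError(
                    f"linear solve residual {res:.2e} exceeds 1e-10; "
                    "the assembled system may be singular"
                )
        return x

    def point_load(self, point) -> np.ndarray:
        """Unit isotropic point source distributed to the containing element
        by barycentric weights."""
        return interpolation_weights(self.mesh, [point])[0]

    def solve_point_source(self, point) -> np.ndarray:
        return self.solve(self.point_load(point))

    def solve_sources(self, points) -> np.ndarray:
        """Fluence fields (n_points, n_nodes) for many point sources."""
        W = interpolation_weights(self.mesh, points)
        return self.solve(W.T).T


def solve_diffusion(
    mesh: Mesh,
    field: OpticalField,
    source_point,
    robin_coefficient: float | None = None,
) -> np.ndarray:
    """Nodal fluence for a unit point source (thin wrapper over
    :class:`DiffusionSolver` for one-off solves)."""
    solver = DiffusionSolver(mesh, field, robin_a=robin_coefficient)
    return solver.solve_point_source(source_point)


def boundary_measurements(
    fluence_by_source: np.ndarray,
    mesh: Mesh,
    optodes: OptodeArray,
    wavelength: float = 0.0,
):
    """Per-link boundary amplitudes, ordered as the link table.

    ``fluence_by_source`` holds one nodal fluence vector per source
    (n_sources, n_nodes); detector readings are linear (P1) interpolations
    of nodal fluence at the detector positions.
    """
    fluence_by_source = np.atleast_2d(np.asarray(fluence_by_source, float))
    if fluence_by_source.shape[0] < optodes.link_table[:, 0].max() + 1:
        raise DimensionError("need one fluence vector per source in the link table")
    Wd = interpolation_weights(mesh, optodes.detector_positions)
    readings = fluence_by_source @ Wd.T  # (n_sources, n_detectors)
    amps = readings[optodes.link_table[:, 0], optodes.link_table[:, 1]]
    return amps
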