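"""Gauss-Newton outer loop for spectrally constrained reconstruction.

Each outer iteration maps concentrations to absorption through Beer's law,
runs the diffusion forward model at every wavelength, forms the data-model
mismatch, rebuilds the spectral Jacobian by the adjoint method, and calls
the configured update solver.  Concentrations are updated additively and
the loop stops when the mismatch stagnates (L1 change below tolerance) or
the iteration cap is reached.  Scattering is computed from the Mie prior at
startup and held fixed: continuous-wave amplitude data cannot separate
scattering from absorption.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import DimensionError, NumericalError, ParameterError
from .fem import DiffusionSolver, OpticalField, boundary_measurements
from .mesh import Mesh, OptodeArray
from .regparam import lcurve_corner, lcurve_scan
from .solvers import SolverSettings, UpdateProblem, solve_update
from .spectral import (
    ChromophoreField,
    ExtinctionTable,
    beer_law_mua,
    spectral_jacobian,
    wavelength_jacobian,
)

__all__ = [
    "MeasurementSet",
    "ReconSettings",
    "ReconResult",
    "data_mismatch",
    "calibrate_measurements",
    "forward_measurements",
    "reconstruct",
]


@dataclass
class MeasurementSet:
    """Boundary amplitudes per link and wavelength.

    ``amplitudes`` has shape (n_links, n_wavelengths), strictly positive,
    in arbitrary units; ``links`` is the (n_links, 2) source/detector index
    table shared by all wavelengths.
    """

    wavelengths: tuple
    links: np.ndarray
    amplitudes: np.ndarray
    noise_meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        self.links = np.asarray(self.links, dtype=np.int64)
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if self.amplitudes.shape != (len(self.links), len(self.wavelengths)):
            raise DimensionError(
                "amplitudes must be (n_links, n_wavelengths); got "
                f"{self.amplitudes.shape}"
            )
        if np.any(self.amplitudes <= 0):
            raise ParameterError("measurement amplitudes must be strictly positive")

    @property
    def n_links(self) -> int:
        return len(self.links)

    def vector(self) -> np.ndarray:
        """Concatenated per-wavelength amplitude vector, first wavelength first."""
        return self.amplitudes.T.ravel()


def _check_compatible(a: MeasurementSet, b: MeasurementSet) -> None:
    if a.wavelengths != b.wavelengths or not np.array_equal(a.links, b.links):
        raise DimensionError("measurement sets have different links or wavelengths")


def data_mismatch(measured: MeasurementSet, computed: MeasurementSet) -> np.ndarray:
    """Concatenated per-wavelength difference measured - computed."""
    _check_compatible(measured, computed)
    return measured.vector() - computed.vector()


def calibrate_measurements(
    het_measured: MeasurementSet,
    hom_measured: MeasurementSet,
    hom_modelled: MeasurementSet,
) -> MeasurementSet:
    """Ratio calibration against a homogeneous reference.

    calibrated = heterogeneous_measured * homogeneous_modelled /
    homogeneous_measured, per link and wavelength; per-link source/detector
    coupling gains cancel in the ratio.
    """
    _check_compatible(het_measured, hom_measured)
    _check_compatible(het_measured, hom_modelled)
    if np.any(hom_measured.amplitudes == 0):
        raise NumericalError("homogeneous measurement contains zeros")
    amps = het_measured.amplitudes * hom_modelled.amplitudes / hom_measured.amplitudes
    return MeasurementSet(het_measured.wavelengths, het_measured.links, amps)


@dataclass
class ReconSettings:
    """Outer-loop configuration.

    lambda_reg may be a number or "auto" (L-curve corner on the first outer
    linearization, then reused).  outer_tol defaults to 1e-6 times the L1
    norm of the measured data; c0 maps chromophore name to a homogeneous
    initial value (or per-node array).
    """

    solver: SolverSettings = dc_field(default_factory=SolverSettings)
    lambda_reg: float | str = "auto"
    max_outer_iter: int = 20
    outer_tol: float | None = None
    c0: dict = dc_field(default_factory=dict)
    data_transform: str = "raw"
    robin_a: float | None = None
    lcurve_ladder: np.ndarray | None = None
    # with lambda_reg="auto", inflate the corner lambda until the first update
    # satisfies ||dc||_inf <= trust_fraction * max background concentration;
    # the default admits updates up to the background level itself, beyond
    # which the linearized forward model is meaningless (None disables)
    trust_fraction: float | None = 1.0
    # optional corner-search window for "auto", as fractions of the ladder
    # top, e.g. (1e-3, 1.0) restricts the corner to the top three decades —
    # the automated stand-in for manually refining toward the strongly
    # regularized side when the data are noise dominated
    lcurve_window: tuple | None = None

    def __post_init__(self) -> None:
        if self.max_outer_iter < 1:
            raise ParameterError("max_outer_iter must be >= 1")
        if self.outer_tol is not None and self.outer_tol <= 0:
            raise ParameterError("outer_tol must be positive")
        if self.data_transform not in ("raw", "log"):
            raise ParameterError("data_transform must be 'raw' or 'log'")
        if isinstance(self.lambda_reg, str) and self.lambda_reg != "auto":
            raise ParameterError("lambda_reg must be a number or 'auto'")


@dataclass
class ReconResult:
    """Reconstruction trajectory and provenance."""

    field: ChromophoreField
    delta_traces: list  # per outer iteration: dict name -> per-node update
    residual_trace: np.ndarray  # ||dphi||_2 per outer iteration
    lambda_used: float
    settings: ReconSettings
    n_outer: int = 0
    converged: bool = False

    def total_change(self) -> dict:
        names = self.field.names
        out = {n: np.zeros(self.field.n_nodes) for n in names}
        for step in self.delta_traces:
            for n in names:
                out[n] = out[n] + step[n]
        return out


def forward_measurements(
    mesh: Mesh,
    field: ChromophoreField,
    optodes: OptodeArray,
    table: ExtinctionTable,
    wavelengths,
    robin_a: float | None = None,
    return_solvers: bool = False,
):
    """Model boundary amplitudes for a chromophore field at each wavelength."""
    amps = []
    solvers = []
    for wl in wavelengths:
        # floor mua at a tiny positive value so transiently overshooting
        # updates cannot make the diffusion system indefinite
        mua = np.maximum(beer_law_mua(table, field, wl), 1e-6)
        musp = np.broadcast_to(
            np.atleast_1d(field.musp(wl)), (mesh.n_nodes,)
        ).astype(float)
        opt = OpticalField(mua, musp, wl)
        solver = DiffusionSolver(mesh, opt, robin_a=robin_a)
        phi = solver.solve_sources(optodes.interior_source_points)
        amps.append(boundary_measurements(phi, mesh, optodes, wl))
        solvers.append(solver)
    ms = MeasurementSet(tuple(wavelengths), optodes.link_table, np.column_stack(amps))
    return (ms, solvers) if return_solvers else ms


def _transformed_vector(ms: MeasurementSet, transform: str) -> np.ndarray:
    v = ms.vector()
    return np.log(v) if transform == "log" else v


def reconstruct(
    measured: MeasurementSet,
    mesh: Mesh,
    table: ExtinctionTable,
    scatter_amplitude,
    scatter_power,
    optodes: OptodeArray,
    settings: ReconSettings,
) -> ReconResult:
    """Gauss-Newton reconstruction of chromophore concentrations.

    ``scatter_amplitude``/``scatter_power`` give the fixed Mie scattering
    prior (scalar or per node).  Initial concentrations come from
    ``settings.c0`` (chromophore name -> homogeneous value or nodal array).
    """
    names = table.chromophores
    missing = [n for n in names if n not in settings.c0]
    if missing:
        raise ParameterError(f"initial concentrations missing for {missing}")
    conc = {
        n: np.broadcast_to(np.atleast_1d(np.asarray(settings.c0[n], float)),
                           (mesh.n_nodes,)).copy()
        for n in names
    }
    field = ChromophoreField(conc, scatter_amplitude, scatter_power)
    wavelengths = measured.wavelengths
    y = _transformed_vector(measured, settings.data_transform)
    outer_tol = (
        settings.outer_tol
        if settings.outer_tol is not None
        else 1e-6 * float(np.abs(measured.vector()).sum())
    )

    lam = settings.lambda_reg
    residuals = []
    deltas = []
    prev_dphi = None
    prev_x = None
    converged = False
    n_outer = 0
    best_misfit = np.inf
    best_state = None  # (concentrations, n_deltas) at the lowest misfit

    for k in range(1, settings.max_outer_iter + 1):
        try:
            computed, solvers = forward_measurements(
                mesh, field, optodes, table, wavelengths,
                robin_a=settings.robin_a, return_solvers=True,
            )
        except (ParameterError, NumericalError):
            if best_state is None:
                raise  # the initial field itself is unusable
            break  # diverged update produced an unphysical field; keep best
        dphi = y - _transformed_vector(computed, settings.data_transform)
        misfit = float(np.linalg.norm(dphi))
        residuals.append(misfit)
        n_outer = k
        if misfit < best_misfit:
            best_misfit = misfit
            best_state = ({n: field.concentrations[n].copy() for n in names}, len(deltas))
        elif misfit > 1.5 * best_misfit:
            # divergence guard: a linearized step that inflates the misfit
            # means the update left the linearization's validity region;
            # keep the best iterate seen so far
            break
        if prev_dphi is not None and np.abs(dphi - prev_dphi).sum() <= outer_tol:
            converged = True
            break
        if np.abs(dphi).sum() <= outer_tol:
            converged = True
            break
        prev_dphi = dphi

        subs = []
        for i, wl in enumerate(wavelengths):
            Jl = wavelength_jacobian(mesh, solvers[i].field, optodes, solver=solvers[i])
            if settings.data_transform == "log":
                Jl = Jl / computed.amplitudes[:, i][:, None]
            subs.append(Jl)
        J = spectral_jacobian(subs, table, wavelengths)

        if isinstance(lam, str):  # "auto": L-curve on the first linearization
            scan_problem = UpdateProblem(J, dphi, 0.0)
            curve = lcurve_scan(scan_problem, settings.solver, settings.lcurve_ladder)
            window = None
            if settings.lcurve_window is not None:
                top = float(curve.lambdas[0])
                window = (
                    top * settings.lcurve_window[0],
                    top * settings.lcurve_window[1],
                )
            lam = lcurve_corner(curve, window=window)
            auto_lambda = True
        else:
            auto_lambda = False

        problem = UpdateProblem(J, dphi, float(lam))
        result = solve_update(problem, settings.solver, x0=prev_x)
        x = result.delta_c
        if auto_lambda and settings.trust_fraction is not None:
            # trust region on the automatic choice: when the data are noise
            # dominated the L-curve corner can prescribe an update far outside
            # the linearization's validity region; inflate lambda until the
            # first step stays within a fraction of the background level
            radius = settings.trust_fraction * max(
                float(np.abs(settings.c0[n]).max()) for n in names
            )
            while np.abs(x).max() > radius:
                lam = float(lam) * 10**0.5
                problem = UpdateProblem(J, dphi, float(lam))
                x = solve_update(problem, settings.solver, x0=None).delta_c
        prev_x = x
        step = {
            n: x[j * mesh.n_nodes : (j + 1) * mesh.n_nodes]
            for j, n in enumerate(names)
        }
        deltas.append(step)
        for n in names:
            field.concentrations[n] = field.concentrations[n] + step[n]

    if best_state is not None and best_misfit < residuals[-1]:
        conc_best, n_deltas = best_state
        for n in names:
            field.concentrations[n] = conc_best[n]
        deltas = deltas[:n_deltas]

    return ReconResult(
        field=field,
        delta_traces=deltas,
        residual_trace=np.asarray(residuals),
        lambda_used=float(lam) if not isinstance(lam, str) else float("nan"),
        settings=settings,
        n_outer=n_outer,
        converged=converged,
    )
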