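"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own code paths: the lasso oracle is
a plain proximal-gradient loop, the Green's function is the closed-form
infinite-medium solution, and the block-matrix oracle is a naive loop.
"""

from __future__ import annotations

import numpy as np
from scipy.special import k0


def lasso_oracle(J: np.ndarray, y: np.ndarray, lam: float,
                 max_iter: int = 200_000, tol: float = 1e-14) -> np.ndarray:
    """High-precision minimizer of ||y - J x||_2^2 + lam ||x||_1 by ISTA."""
    L = 2.0 * float(np.linalg.eigvalsh(J.T @ J)[-1])
    t = 1.0 / L
    x = np.zeros(J.shape[1])
    for _ in range(max_iter):
        g = 2.0 * J.T @ (J @ x - y)
        z = x - t * g
        x_new = np.sign(z) * np.maximum(np.abs(z) - t * lam, 0.0)
        if np.abs(x_new - x).max() < tol:
            return x_new
        x = x_new
    return x


def lasso_objective(J, y, lam, x) -> float:
    r = y - J @ x
    return float(r @ r + lam * np.abs(x).sum())


def greens_function_2d(r: np.ndarray, mua: float, musp: float) -> np.ndarray:
    """CW diffusion Green's function for a unit point source in an infinite
    2D medium: K0(mueff r) / (2 pi kappa)."""
    kappa = 1.0 / (3.0 * (mua + musp))
    mueff = np.sqrt(mua / kappa)
    return k0(mueff * np.asarray(r)) / (2.0 * np.pi * kappa)


def spectral_block_oracle(sub_jacobians, eps_matrix) -> np.ndarray:
    """Naive loop assembly of the spectral block matrix.

    ``eps_matrix[i][j]`` is the extinction coefficient of chromophore j at
    wavelength i.
    """
    rows = []
    for i, Jl in enumerate(sub_jacobians):
        row = [np.asarray(Jl) * eps_matrix[i][j] for j in range(len(eps_matrix[i]))]
        rows.append(np.hstack(row))
    return np.vstack(rows)
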