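"""The four update solvers on one small regularized inverse problem.

Builds a random overdetermined system, solves the L1-regularized update
with IRLS, ADMM and FISTA (and the L2 Tikhonov update for contrast), and
compares objectives.  The L1 solvers implement their standard printed
updates, whose effective L1 weight relative to ||r||^2 + lam ||x||_1 is
2 lam — hence the lam/2 passed below.
"""

import numpy as np

import scdot as sd

rng = np.random.default_rng(0)
J = rng.standard_normal((20, 12))
y = rng.standard_normal(20)
lam = 0.1 * np.abs(2.0 * J.T @ y).max()


def objective(x):
    r = y - J @ x
    return r @ r + lam * np.abs(x).sum()


print(f"problem: {J.shape[0]} measurements, {J.shape[1]} unknowns, lam={lam:.3f}")
tik = sd.tikhonov_update(sd.UpdateProblem(J, y, lam))
print(f"tikhonov: obj={objective(tik.delta_c):.6f} "
      f"zeros={np.sum(tik.delta_c == 0)}  (L2: no exact zeros)")

problem = sd.UpdateProblem(J, y, lam / 2.0)
for method, solve in (("irls", sd.irls_solve), ("admm", sd.admm_solve),
                      ("fista", sd.fista_solve)):
    settings = sd.SolverSettings(method=method, tol=1e-12, max_inner_iter=5000,
                                 epsilon_irls=0.001)
    res = solve(problem, settings)
    print(f"{method:8s}: obj={objective(res.delta_c):.6f} "
          f"zeros={np.sum(res.delta_c == 0)} inner_iters={res.iterations_used}")
# the three L1 solvers agree on the objective; ADMM/FISTA return exact zeros
# (soft thresholding), IRLS drives small entries toward zero smoothly
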