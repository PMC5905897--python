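"""Choosing the regularization weight with the L-curve.

Scans a descending lambda ladder on a noisy linear problem, prints the
misfit/regularizer trade-off, and locates the maximum-curvature elbow.
"""

import numpy as np

import scdot as sd

rng = np.random.default_rng(3)
n = 40
# smooth ill-posed forward operator + sparse truth + noise
J = np.array([[np.exp(-0.5 * ((i - j) / 3.0) ** 2) for j in range(n)] for i in range(n)])
x_true = np.zeros(n)
x_true[[8, 22]] = [1.0, -0.7]
y = J @ x_true + 0.01 * rng.standard_normal(n)

problem = sd.UpdateProblem(J, y, 0.0)
curve = sd.lcurve_scan(problem, sd.SolverSettings(method="fista", tol=1e-10,
                                                  max_inner_iter=3000))
lam_star = sd.lcurve_corner(curve)
k = curve.curvature()

print("lambda      misfit      |x|_1    curvature")
for i in range(len(curve.lambdas)):
    mark = " <-- corner" if np.isclose(curve.lambdas[i], lam_star) else ""
    kk = f"{k[i]:+.2f}" if np.isfinite(k[i]) else "  - "
    print(f"{curve.lambdas[i]:.3e}  {curve.residuals[i]:.3e}  {curve.regularizers[i]:7.3f}  {kk}{mark}")
print(f"\ncorner lambda = {lam_star:.4e}")
print("large lambda: everything shrunk to zero (misfit = |y|^2);")
print("small lambda: noise fitted (regularizer blows up); the elbow balances both")
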