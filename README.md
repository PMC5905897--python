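# scdot — spectrally constrained diffuse optical tomography with sparse reconstruction

`scdot` reconstructs maps of oxy- and deoxyhemoglobin concentration
(HbO₂, Hb, in mM) from multi-wavelength continuous-wave near-infrared
boundary measurements — the inverse problem behind functional diffuse
optical imaging of the brain, breast and tissue phantoms.  It is aimed at
researchers who want a compact, fully testable implementation of the
spectral-L1 reconstruction approach: a finite-element diffusion forward
model, a spectrally constrained Gauss–Newton loop, and interchangeable
sparse (L1) and quadratic (L2) update solvers, together with a synthetic
phantom generator so the entire pipeline runs without any external data.

## The model

Light transport is the continuous-wave diffusion approximation with a
Robin (type III) boundary condition,

    −∇·κ(r,λ) ∇Φ(r,λ) + μa(r,λ) Φ(r,λ) = q₀(r,λ),     κ = 1/[3(μa + μs′)],

discretized with P1 finite elements.  The spectral constraint couples the
wavelengths through Beer's law, μa(λ) = ε_HbO₂(λ)·c₁ + ε_Hb(λ)·c₂, and
through the Mie power law μs′ = A·(λ/1000 nm)^(−b) for the (fixed)
scattering.  Each Gauss–Newton iteration linearizes the boundary data
around the current concentrations, builds the block spectral sensitivity
matrix J (adjoint method, exact derivative of the discrete system), and
solves the regularized update problem

    Δc = argmin ‖ΔΦ − J Δc‖₂² + λ·R(Δc)

with R = ‖·‖₂² (Tikhonov) or R = ‖·‖₁ via one of three solvers: IRLS
(iteratively reweighted least squares), ADMM (alternating direction method
of multipliers with soft-threshold shrinkage), or FISTA (accelerated
proximal gradient).  The weight λ is chosen at the maximum-curvature
corner of the L-curve, scanned once on the first linearization.
Reconstruction quality is scored by average contrast (AC), Pearson
correlation (PC) and PSNR.

## A worked example

`examples/05_phantom_reconstruction.py` simulates the standard phantom — a
25 mm disk with gray-matter optics, a ring of 16 sources and 16 detectors,
and one 4 mm inclusion carrying +5 µM HbO₂ — on a fine mesh, calibrates
against the homogeneous reference, and reconstructs with FISTA:

```
reconstruction mesh: 347 nodes; links: 240 x 2 wavelengths
lambda chosen: 6.550e-04; outer iterations: 7
recovered peak at (10.0, 0.0) mm — truth centre (10.0, 0.0)
AC  = 1.223   (1 = perfect region-mean contrast)
PC  = 0.918   (correlation with the true map)
PSNR= 24.3 dB
```

The recovered activation peaks exactly at the true inclusion centre with a
region-mean contrast within ~20% of truth.  `examples/06_noise_robustness.py`
repeats this at 1% proportional measurement noise and shows the
characteristic contrast between regularizers — the L2 solution smears noise
across the image (PSNR ≈ −11 dB) while the sparse solver keeps the
activation compact (PSNR ≈ 21 dB):

```
--- tikhonov
  seed 0: AC=-0.823  PSNR= -10.1 dB
--- fista
  seed 0: AC=+0.970  PSNR=  22.3 dB
```

The remaining examples each demonstrate one layer: the forward model
against the analytic Green's function (`01`), Beer's law and Mie scattering
(`02`), the four update solvers on a small problem (`03`), and L-curve
corner detection (`04`).

A thin CLI wraps the same pipeline for shell use
(`scdot run config.yaml`, plus `simulate`, `lcurve`, `reconstruct`,
`evaluate` subcommands); see `scdot --help`.

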