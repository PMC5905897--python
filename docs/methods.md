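# Methods

This note documents the models, numerical choices and limitations behind
`scdot`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic studies do and do not demonstrate.

## Forward model

Continuous-wave photon transport is modelled by the diffusion
approximation with an index-mismatched Robin boundary condition, valid when
scattering dominates absorption (μs′ ≫ μa) and observation points are at
least a transport length from sources — both satisfied by the tissue-like
parameter ranges used throughout (μa ≈ 0.004–0.021 mm⁻¹,
μs′ ≈ 0.3–1.2 mm⁻¹).

Discretization is P1 (linear nodal) finite elements on triangles (2D) or
tetrahedra (3D), through one dimension-generic assembly path.  All terms
are integrated exactly for P1 fields: the stiffness term uses the element
mean of the nodal diffusion coefficient κ = 1/[3(μa+μs′)]; the absorption
mass term uses the exact triple-product integrals
∫φₖφᵢφⱼ = d!·V·{6,2,1}/(d+3)! so that nodally varying μa enters
consistently; the Robin term adds facet mass matrices scaled by 1/(2A).
The reflection parameter A comes from the Groenhuis–Keijzer polynomial fit
of the internal diffuse reflection coefficient, default relative refractive
index 1.33 (A ≈ 2.82); A = 1 or any explicit value is selectable because
published implementations differ in this convention.

Sources are unit isotropic point loads placed one transport length 1/μs′
inside the boundary, distributed to the containing element by barycentric
weights.  Detector readings are P1 interpolations of nodal fluence at the
detector position.  Because the load and measurement functionals are the
same barycentric-weight construction and the system matrix is symmetric,
discrete reciprocity holds to machine precision.  Optodes are kept at
their exact analytic positions; point location clips marginally exterior
points (a circle point off the polygonal hull by O(h²)) onto the nearest
element, which is what makes simulation and reconstruction meshes of
different resolution share one optode geometry.

Verification: on a homogeneous 25 mm disk (≥10 transport lengths), the
central-source solution agrees with the infinite-medium Green's function
K₀(μ_eff r)/(2πκ) to ≈2% (max) in the 5–10 mm annulus at 2 mm resolution,
and the error decreases under mesh refinement.  Global positivity of the
discrete fluence is observed on the meshes used here but is not a theorem
for consistent-mass P1 FEM; ultra-coarse meshes (e.g. a five-tetrahedron
cube) can show small negative far-field values.

## Spectral model and Jacobian

Absorption couples to the two chromophores through Beer's law; the shipped
extinction table (base-e, mm⁻¹·mM⁻¹: HbO₂ 0.1193/0.2437, Hb 0.3236/0.1591
at 750/850 nm) is the standard compiled hemoglobin dataset used in
functional neuroimaging, and reproduces the per-tissue absorption
coefficients of the head-tissue table from its printed concentrations to
printed precision.  A single-chromophore "generic dye" table supports
phantom experiments where the dye has unit concentration and its
extinction equals the bulk absorption.  Scattering follows
μs′ = A·(λ[µm])^(−b) — the micrometre convention reproduces all printed
tissue μs′ values — and is never updated by reconstruction: CW amplitude
data cannot separate scattering from absorption.

The per-wavelength sensitivity J_λ[m,n] = ∂(amplitude of link m)/∂μa(node n)
is assembled by the adjoint method as the exact derivative of the discrete
system: the absorption mass term −Ψᵀ(∂M/∂μaₙ)Φ plus the diffusion term
from ∂κ/∂μa = −3κ², with forward fields Φ per source and adjoint fields Ψ
per detector from a single factorization.  The κ term contributes ~2%
relative (3κμa) and is included so that finite-difference checks agree to
solver precision rather than to 2%.  The spectral Jacobian stacks the
J_λ scaled by the extinction coefficients into the block matrix with one
row block per wavelength and one column block per chromophore.  In
log-amplitude mode each row of J_λ is divided by the modelled amplitude.

## Update solvers and the λ convention

The four update solvers implement their standard printed iterations:

* Tikhonov: (JᵀJ + λI)Δc = JᵀΔΦ, by Cholesky with a residual contract of
  1e-10 relative.
* IRLS: repeated weighted-L2 solves with wₛ = |Δcₛ|^(−1/2) floored at 1/ε;
  ε fixed (default 0.005, results insensitive over 0.001–0.01);
  initialized from the Tikhonov update; at most 20 reweightings.
* ADMM: splitting with shrinkage soft(Δc + b, λ/θ) and multiplier update;
  the returned solution is the split variable v, which equals Δc at
  convergence and carries the exact-zero sparsity pattern.  The penalty θ
  is dimensionless — the absolute penalty is θ·‖JᵀJ‖₂ — so convergence
  behaviour is invariant to the data scale; default θ = 0.01.
* FISTA: accelerated proximal gradient with ∇F = Jᵀ(JΔc − ΔΦ), threshold
  t·λ, Nesterov momentum α update, step t = 0.9/L with L estimated by
  power iteration, and backtracking halving t until the quadratic
  majorization of the smooth part holds.  Stopping uses the relative
  change of the iterate (the "relative residual" of the usual statement of
  the algorithm left unspecified; this is the documented choice).

Convention: relative to the objective ‖r‖₂² + λ‖Δc‖₁, all three L1
solvers as printed carry an effective L1 weight of 2λ (ADMM/FISTA because
their gradient omits the factor 2; IRLS because the fixed point of the
|Δc|^(−1/2) reweighting satisfies −2Jᵀr + 2λ·sign(Δc) = 0).  Cross-solver
comparisons at a common objective therefore pass λ/2 to the L1 solvers.
In practice λ is selected per solver by the L-curve, which absorbs the
convention.  On random small problems all three reach the independent
proximal-gradient oracle's objective to better than 1e-3 relative
(typically 1e-6 or better).

## Gauss–Newton outer loop

Each outer iteration recomputes μa from the current concentrations
(floored at 1e-6 mm⁻¹ so a transiently overshooting update cannot make the
system indefinite), runs the forward model per wavelength, forms the
data–model mismatch (first wavelength block first), rebuilds the spectral
Jacobian, solves the regularized update, and adds it to the concentration
fields.  The loop stops on mismatch stagnation (L1 change below
outer_tol, default 1e-6·‖Φᴹ‖₁) or the iteration cap (default 20).  Two
safeguards go beyond the textbook loop: the iterate with the lowest
misfit is tracked and restored if later iterations are worse, and the loop
breaks when the misfit exceeds 1.5× the best seen — linearized updates
that inflate the nonlinear misfit have left the validity region of the
linearization, and continuing only accumulates noise-fit.

Data can be fitted as raw amplitudes (the default, matching the literal
difference form of the mismatch) or as log amplitudes.  For proportional
("x%") measurement noise the log-amplitude misfit is the correctly
whitened likelihood, and it is the mode used by the bundled studies: in
raw mode the absolute noise on near links drowns the information carried
by far links.

λ = "auto" scans the L-curve on the first linearization only and reuses
the corner λ for all remaining outer iterations; the scan ladder starts at
‖JᵀΔΦ‖∞ (the smallest weight with an all-zero L1 solution under the
implemented convention) and descends by 10^0.25 per point, 25 points.  A
trust region guards the automatic choice: if the first update exceeds
trust_fraction × max(c₀) in infinity norm (default 1.0 — an update at the
background level itself, beyond which absorption can go negative), λ is
inflated by √10 steps until it does not.  An optional corner-search window
(as fractions of the ladder top) restricts the search; the studies use the
top three decades, standing in for the manual refinement toward strongly
regularized, compactly localized solutions that practitioners apply when
the curve has no clean numerical optimum.

Initial concentrations come from the user (homogeneous background for
synthetic studies); an outer-loop calibration against a homogeneous
reference — calibrated = measured_het × modelled_hom / measured_hom per
link — removes source/detector coupling factors and the model/data
mismatch, and is what allows reconstruction on a coarser mesh than the
data were generated on.

## L-curve corner detection

The L-curve records ‖ΔΦ − JΔc‖₂² against ‖Δc‖₁ (L1 solvers) or ‖Δc‖₂²
(Tikhonov) over the descending ladder, warm-starting each solve.  Corner
detection works on the log10–log10 polyline: points with an all-zero
solution (regularizer 0) carry no geometry and are excluded; remaining
points are thinned so no two retained points are closer than a quarter of
the curvature scale (densely clustered points wobble at solver tolerance);
the signed curvature at each retained point is the Menger
(circumscribed-circle) curvature of the triple formed with the nearest
retained neighbours at least one scale away on each side, with the sign
convention that an L-elbow is positive.  The scale defaults to a tenth of
the curve's arc length — curvature is measured at the macroscopic bend,
not at sampling wobble.  The corner is the positive-curvature maximum
(ties toward larger λ); if no point has positive curvature the failure is
explicit (`NoCornerError`), which genuinely occurs for noise-free
inverse-crime data (Tikhonov) and for the floor-dominated IRLS curve on
noise-free calibrated data.

## Synthetic phantoms and noise

The generator emulates bench-scale versions of head-imaging studies: a
25 mm disk (optionally layered annuli) with per-region backgrounds
defaulting to the gray-matter row of the head-tissue table (c₁ = 0.0548 mM,
c₂ = 0.0354 mM, A = 0.5040, b = 1.7757), disk inclusions that add
(e.g. ±5 µM) or multiply (e.g. doubling) the background, a ring of 16
sources and 16 detectors (240 links after excluding co-located pairs), and
wavelengths 750/850 nm.  The standard phantom places one 4 mm inclusion
with Δc₁ = +5 µM at (10, 0) mm.  The reconstruction mesh uses 2.5 mm
edges (~350 nodes) so the full pipeline runs in seconds; simulation uses
1.4 mm edges so recovery tests are not inverse crimes.

Noise is proportional Gaussian: amplitude × (1 + level·z) independently
per link and wavelength, either flat (e.g. 1%) or binned by
source–detector distance with edges at the midpoints between nominal
nearest-neighbour distances (bins [0, 21.5, 35, 44, ∞) mm at
0.12/0.15/0.41/1.42%).  Amplitudes driven non-positive are clipped to a
small positive floor with a warning.

What the studies show — and do not.  The noise study (ten seeds at 1%
flat noise, λ per solver from the first realization with a usable corner,
reused across seeds) reproduces the qualitative ordering reported for
this class of methods: every L1 solver beats Tikhonov on median AC and
median PSNR, with FISTA closest to unit contrast and IRLS over-sparse and
contrast-overshooting.  At this phantom's contrast (5 µM on a 55 µM
background, peak link perturbation ≈1.7%) 1% noise leaves individual
reconstructions strongly regularized and seed-dependent; the medians, not
single runs, carry the conclusion.  None of this demonstrates performance
on real tissue: the generator has exact Beer's-law/Mie physics, no
physiological fluctuations, no optode miscalibration beyond what the
ratio calibration removes, and desk-scale geometry rather than
anatomical meshes.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| ε (IRLS floor) | 0.005 | weights capped at 1/ε; fixed across iterations |
| θ (ADMM penalty) | 0.01 | relative to ‖JᵀJ‖₂ |
| FISTA safety | 0.9 | step t = 0.9/L, backtracking on |
| inner iterations | 200 (IRLS 20) | tolerance 1e-6 on iterate change |
| outer iterations | 20 | outer_tol 1e-6·‖Φᴹ‖₁ |
| ladder | ‖JᵀΔΦ‖∞ ÷ 10^0.25 ×25 | L-curve scan, first linearization only |
| trust_fraction | 1.0 | cap on the first auto-λ update, ∞-norm |
| Robin A | n = 1.33 fit | A = 1 selectable |
| data_transform | raw | "log" recommended under proportional noise |

## Known limitations

Two wavelengths and two chromophores are the tested configuration (the
block structure generalizes but water/lipids are out of scope).  The
diffusion model excludes low-scattering regions such as CSF from faithful
treatment.  No frequency- or time-domain data; no scattering
reconstruction; no Lp (0<p<1) or total-variation regularization.  The
L-curve can legitimately fail on noise-free inverse-crime data, and the
reconstruct-only pipeline mode requires a phantom spec for its geometry.
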