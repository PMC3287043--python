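# Methods

## Model

The myocardial wall between the endocardial and epicardial surfaces is
represented as a trivariate tensor-product B-spline

V(t, w, u) = Σᵢ Σⱼ Σₗ pᵢⱼₗ Nᵢ,ₖ₁(t) Nⱼ,ₖ₂(w) Nₗ,ₖ₃(u),

with t the circumferential, w the long-axis and u the transmural (radial)
parameter, each on [0, 1]. Basis functions follow the Cox–de Boor recursion
with the 0/0 := 0 convention; the degree-0 indicator is half-open and closed
at the global right endpoint so the full domain boundary is evaluable.
Derivatives use the standard two-term lower-degree formula, with vanishing
denominators contributing zero. The circumferential direction is periodic:
uniform knots with degree-wide padding and control arrays that repeat their
first k₁ columns, so evaluation wraps seamlessly around the ventricle.
Degrees default to cubic (k₁ = k₂ = k₃ = 3) in every direction and are
configurable; cubic is the lowest degree giving C² fields, which strain
evaluation (first derivatives) benefits from.

A cylindrical-coordinate form of the solid (control values r, θ, z, with
θ computed by the quadrant-resolving branch table and then unwrapped along
the circumferential control index so no 2π jumps appear between neighbouring
control angles) is provided for shape description and reporting. Strain and
stress are always evaluated in Cartesian coordinates; no cylindrical strain
operator is defined.

## From contours to a solid

**Parameterization.** Each wall point receives t = θ/2π from its azimuth and
w from the normalized chord length along the z-ordered slice centroids.
Slice and ring indices are taken from segmentation order; when absent, rings
are re-ordered by nearest angle and slices inferred by clustering z at its
dominant gaps.

**Surface fitting.** For a fixed parameterization the control net minimizing
Σₚ ‖S(tₚ, wₚ) − xₚ‖² is linear; it is solved with a rank-revealing
least-squares factorization (mathematically the normal-equations minimizer,
numerically better conditioned). The periodic circumferential basis is
folded modulo the number of unique control columns, so the wrap constraint
is built into the design matrix rather than imposed afterwards. Open-clamped
longitudinal knots are uniform by default; knot placement by parameter
averaging (Riesenfeld) or chord-length-weighted averaging (Hartley–Judd) is
available where fitted parameters are strongly non-uniform.

**Cross-phase correspondence.** Later phases are fitted with the *reference
phase's* (t, w) parameters, keyed by slice/ring indices, i.e. the contour
points are treated as tracked material points. Re-deriving parameters from
the deformed geometry would break material correspondence entirely — a pure
twist of a circular ring maps the ring onto itself and would register as
zero motion. With shared parameters and shared knots/degrees/net sizes, all
phases have identical control topology and control-point differences are a
valid displacement field. A useful side effect is that the part of the fit
error common to both phases cancels in the difference, which is why
recovered strain is an order of magnitude more accurate than the raw
surface-fit residual would suggest.

**Sweeping and solid assembly.** Radial layer q of L is the linear blend
(1 − q/(L−1))·inner + (q/(L−1))·outer of matched control points; layer 0 is
exactly the inner net and the last layer the outer net. The swept mesh is
adopted directly as the solid's control grid (no volumetric re-fit), with
the radial knot vector built by parameter averaging over the uniform layer
parameters. Crossing walls (inner radius exceeding outer at matched control
points) trigger a warning, and the trilinear cell-Jacobian check flags
tangled meshes.

## Strain and stress

The displacement field shares the geometry's basis (isogeometric analysis):
control displacements dᵢⱼₗ are the differences of the two phases' control
points, and Disp(t꜀,tₗ,tᵣ) = Σ dᵢⱼₗ Nᵢ Nⱼ Nₗ. Physical gradients follow
from parametric ones through the isoparametric Jacobian J (columns
∂(x,y,z)/∂t꜀, ∂/∂tₗ, ∂/∂tᵣ): the gradient transform is implemented as the
solve Jᵀ∇ₓN = ∇ₜN, the unique form consistent with the chain rule (it
reduces to division by the scale factors on axis-aligned boxes and passes
the affine patch test on sheared solids; for displacement gradients it is
applied as G_x = G_t J⁻¹).

The Voigt strain uses engineering shears γ = sum of cross-derivatives;
tensor reconstruction for principal values halves them. Stress is σ = Dε
with the isotropic stiffness

D = E(1−μ)/((1+μ)(1−2μ)) · [[A, 0], [0, H·I₃]],  H = (1−2μ)/(2(1−μ)),

where A has unit diagonal and μ/(1−μ) off-diagonal. Defaults are
E = 11 kPa and μ = 0.49, the standard passive-myocardium setting; μ is
restricted to [0, 0.5) because D is singular in the incompressible limit.
Strain and stress are *kinematic* quantities derived from observed motion;
no equilibrium boundary-value problem is solved. Because "principal strain
in the x direction" is ambiguous, exports carry both the raw ε_x/σ_x
component fields and the eigen-principal fields, labelled distinctly.

## Numerical choices

- Volume integration: Gauss–Legendre quadrature of det J applied per knot
  span (the integrand is piecewise polynomial), default order 4 per span per
  direction; order 4 → 6 changes a fitted annulus volume by < 0.1%.
- Jacobians with |det J| < 10⁻¹² raise a singular-mapping error naming the
  parameter point; negative det J during integration is likewise fatal.
- Field lattices sample the periodic direction on [0, 1) (seam duplicate
  excluded) and closed directions on [0, 1]; lattice entries are
  bit-identical to pointwise calls.
- Principal values use the symmetric eigensolver; eigenvalues are returned
  descending with orthonormal directions.
- On the long axis (x = y = 0) the azimuth is defined as θ = 0; ventricular
  walls never contain the axis, so this only guards synthetic edge cases.

## Synthetic ground truth

The generator emulates segmented short-axis cine MRI: truncated prolate
spheroid walls (defaults: inner semi-axes 20/20/45 mm, outer 30/30/55 mm,
a mid-sized adult left ventricle), 12 slices of 32 points equally spaced in
azimuth, truncation fraction 0.85 of the inner long axis from the apex with
an 8% apical stand-off, optional isotropic Gaussian noise added in Cartesian
space after on-surface placement, all driven by one seed. Prescribed
inter-phase maps — rigid translation, uniform dilation, long-axis torsion
(rotation by τ·z), in-plane radial contraction — have closed-form
infinitesimal strain implemented without small-parameter approximation.

What the generator does not emulate: fibre-driven anisotropic motion,
through-plane misregistration, papillary muscles and trabeculation, and any
image/pixel content. Passing recovery tests therefore demonstrates the
correctness of the modelling and analysis chain on smooth wall geometries
with tracked contour points, not robustness to segmentation failure modes.

**Recovery experiment.** The packaged experiment deforms the tracked cloud,
refits both phases as above, and compares evaluated strain to the analytic
field on a 7×5×4 lattice over the interior parameter box [0.1, 0.9]³ — the
margin excludes least-squares edge effects, which are fitting artifacts
rather than method error. Errors are reported relative to the characteristic
imposed strain scale (median of the ground truth's largest component), which
coincides with the imposed fraction for dilation/contraction and equals the
imposed shear scale τ·r for torsion (τ itself, in rad/mm, is not
commensurable with strain). Under the default conditions: affine maps are
recovered to round-off; torsion at 0.01 rad/mm to ~0.8% noise-free and
~1.2% at σ = 0.2 mm contour noise.

## Problem sizes

Default experiment sizes — 12×32-point clouds, 8×6 cubic nets, 4 radial
layers, 7×5×4 evaluation lattices, order-4 quadrature — keep every stage
well-determined (≈390 points against 48 surface degrees of freedom) while
the full validation suite runs in seconds; all sizes are configurable.

## Known limitations

- Small-strain (infinitesimal) theory only; no finite-strain measures and
  no Lagrangian accumulation across more than two phases (phases are
  analysed as adjacent pairs).
- Isotropic linear elasticity; no fibre architecture, activation or
  regional heterogeneity.
- Single-patch topology: papillary muscles, valve anatomy and the right
  ventricle are out of scope.
- Surface fitting assumes contours ordered consistently around the
  circumference; grossly shuffled segmentations are only recovered by the
  nearest-angle fallback.
- The stored model is not rational (no NURBS weights), so circles are
  approximated, not exact; with 8 cubic circumferential columns the radius
  error is below 0.5%.
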