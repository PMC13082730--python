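# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `tipwall`.

## Mechanical model

The cell wall is treated as a thin axisymmetric membrane loaded by a
uniform turgor pressure `P`.  Tensions (stress integrated over the wall
thickness) along the meridional and circumferential directions satisfy
the Young–Laplace relations; the material is 2D-isotropic with a surface
bulk modulus `K_h` (resistance to area change) and surface shear modulus
`mu_h` (resistance to in-plane shape change).  For small strains the pair
is equivalent to a surface Young modulus and Poisson ratio through
`mu_h = Eh/(2(1+nu))`, `K_h = Eh/(2(1-nu))`.  All internal quantities are
nondimensional: lengths by the cell radius `L` (the asymptotic shank
radius), curvatures by `1/L`, tensions and moduli by `P*L`.  Conversion
to MPa (`K = P_dim * L / h * K_h`) is a formatting layer only.

Two inferences follow from inverting the constitutive law:

* `K_h = (sigma_s + sigma_theta) / (2 (lambda_s lambda_theta - 1))` —
  stable wherever the area strain is appreciable; singular as the area
  stretch approaches 1, which happens at stiff tips.
* `mu_h = (sigma_s - sigma_theta) / (1/lambda_theta^2 - 1/lambda_s^2)` —
  intrinsically singular at the apex, where symmetry forces isotropy.
  The library exposes it but reports it only where the anisotropy
  exceeds a configurable tolerance (1e-8 on the denominator); the
  default reporting path suppresses it, and the bulk modulus is the
  deliverable.

Singularity tolerances: |lambda_s lambda_theta - 1| < 1e-6 is treated as
singular.  Non-physical samples (negative `K_h`, area stretch below 1)
are removed, never clipped, and removal fractions are reported — the
removal bias is itself a studied effect (see "False gradients").

## Forward simulator

Synthetic cells make the ground truth knowable.  The unturgid meridian is
the hyphoid `x(y) = (pi y cot(pi y) - 1)/a` with `a = 4.1` (caulonema,
tapered) or `a = 5.7` (chloronema, rounder).  The curve approaches its
cylindrical asymptote like `1/(1-y)`, so it must be truncated: the
default cut is at 93% of the asymptotic radius, giving cells of ~3.4
(caulonema) and ~2.4 (chloronema) radii — the aspect ratio of real
protonemal tip segments.  The solver internally pads the shank by 4 radii
so the far-field boundary condition cannot pollute the reported region.

Outlines and marker stations are discretized **uniformly in the radius
coordinate y** (the hyphoid's natural parameter): 129 outline stations
and 17 marker stations by default.  Stations therefore crowd at the apex
(where geometry changes fastest) and spread along the shank.  This
matters: with arclength-uniform stations the apex triangles are large
enough that the chordal approximation of the wall biases the measured
area stretch by ~1%, which the small apex area strain amplifies into a
>10% modulus error; the y-uniform layout keeps the noise-free pipeline
error near 1%.

### Turgid equilibrium solve

Given modulus profiles on the unturgid outline, the turgid configuration
solves, at every material station, equality between the constitutive
tensions (with `lambda_theta = r_t/r_u` and `lambda_s = ds_t/ds_u`) and
the Young–Laplace tensions of the turgid geometry.  The problem is posed
as a two-point boundary value problem in the unturgid arclength `S` with
state `(r, phi)` (turgid radius and tangent angle):

* the axial force balance `sigma_s = P r/(2 sin phi)` is solved pointwise
  for `lambda_s` by a scalar Newton iteration (the tension is monotone in
  `lambda_s`, so the root is unique);
* the normal balance supplies `d(phi)/dS`;
* the apex stretch `lambda_0` is an unknown parameter fixed by apex
  regularity (isotropy plus `kappa_0 = P/(2 K_h(0) (lambda_0^2 - 1))`),
  with the integration started at a small offset from the regularized
  apex series;
* the padded far field imposes `phi = pi/2`.

`scipy.integrate.solve_bvp` (collocation, tolerance 1e-9) solves the
system, with continuation in pressure as a fallback.  An apex-to-shank
shooting formulation is unstable (the cylindrical far field is a saddle),
which is why collocation was chosen.  Every solution is checked to have a
pointwise constitutive-vs-Young–Laplace residual below 1e-6; zero
pressure returns the identity map.  Modulus profiles are constant, linear
in the axial coordinate (ramp saturating smoothly at an optional
`ramp_length`), or logistic ("nonlinear") with midpoint 0.8 radii from
the apex and width 0.15, so that side and tip plateaus dominate the cell.
The shear modulus follows a constant Poisson ratio (default 0.5; the
radius-change baseline study uses 0).

### Observables and noise

The solved meridians are revolved into 3D outline clouds (256 azimuthal
samples; 257 stations after 2x upsampling of the 129) and marker-ring
candidates (16 per ring, one random azimuthal phase per ring).  Marker
subsets are drawn randomly subject to a minimum pairwise distance;
named triangulation classes small/medium/large = (155, 0.12), (110,
0.22), (55, 0.42) markers/minimum-distance give well-separated mean
nondimensional triangle areas (~0.06 / 0.10 / 0.3).

Marker noise is Gaussian per axis, SDs in units of the cell radius, z
(optical axis) worse than x-y.  The turgid configuration always carries
the localization-software level (0.002 x-y, 0.005 z); the unturgid
configuration carries the level under study: `low` equals the software
level, `medium` and `high` scale the x-y SD by 2.5x and 5x with z twice
x-y.  The medium/high magnitudes are calibration choices (the
experimental estimates are not printed as numbers); they are preset
defaults, fully configurable.  Outline bias shifts a whole detected
outline along its normals by a per-cloud random sign, amplitude equal to
the level's x-y SD.

Cohorts draw per-cell radii uniformly from [0.8, 1.2] L and derive
per-cell RNG streams from one master seed.

What the generator does *not* emulate: anisotropic or thickness-graded
walls, growth between acquisitions, non-axisymmetric cells, spatially
correlated detector noise, and partial marker visibility (synthetic
markers cover the full azimuth).  Passing tests therefore validate the
estimator's geometry and noise response, not those confounders.

## Pipeline numerics

* **Projection/triangulation.**  Markers are flattened to polar
  coordinates (azimuth about the optimized axis; radius a monotone
  meridian coordinate: stereographic `2R tan(gamma/2)` about the
  tip-sphere center up to 80 deg, then a slope-matched linear
  continuation in axial distance).  The map is injective for tube-like
  cells, and its 2D Delaunay triangulations have higher median
  compactness than 3D-hull surface triangulations of the same markers.
  Faces with compactness `4 pi A / P^2 < 0.2` are dropped as seam
  slivers.
* **Deformation.**  `F = B A^-1` per face with independently
  outward-oriented normals; principal stretches from the Cauchy–Green
  eigenstructure.  The noise-amplification bound
  `Gamma = |A^-1| (c_B + |F| c_A)/|F|` (with `c_X` a Frobenius bound on
  the per-unit-displacement perturbation of the basis matrix, including
  the normalized-cross-product normal) guarantees
  `d(lambda1 lambda2)/(lambda1 lambda2) <= 2 Gamma |delta|`; faces above
  the 90th percentile of the per-cell Gamma distribution are removed,
  which preferentially retains compact faces.
* **Curvature.**  Outline clouds are split into five orientation charts
  (tip cap + four sides, 60-degree alignment), resampled as height
  fields on a grid of pitch L/50 with C1 Clough–Tocher interpolation,
  differentiated by centered differences at a stride of 3 grid units
  evaluated at every 1-unit shift, and diagonalized
  (`W = I^-1 II`, sign fixed so convex surfaces are positive).  Euler's
  relation rotates principal curvatures into meridional/circumferential
  components using the angle to the tangent-projected tip direction.
  Per-point tensions are averaged over the wall points each face covers;
  a wall point belongs to a face only if it projects inside it *and*
  lies within a quarter mean-edge of its plane (rejecting apex-crown
  points that hover above surrounding chords).
* **Reduction and binning.**  The long axis is the isolated eigenvalue
  of the cloud's second-moment tensor (the transverse pair is
  degenerate); the tip is the point of maximal axial projection.  Alpha
  runs over [0, 90] degrees in nine 10-degree bins; each face spreads
  over the bins its alpha range overlaps, weighted by fractional
  overlap.  The side region is alpha >= 80 deg; endpoint values are the
  weight-averaged side bins and the apex-most nonempty bin.
* **Bulk-modulus profile.**  The non-physical filter acts per triangle,
  but the inference division is applied to *binned* tension sums and
  area stretches (and, across cohorts, to the run-averaged bins).
  Dividing per triangle leaves an integrable-divergent tail — retained
  area strains arbitrarily close to zero produce unbounded moduli that
  no averaging tames.  Per-triangle division is still computed and
  reported as the `K_h_face` profiles, and the triangle-area variant
  (`S_B/S_A` in place of the stretch product) as `K_h_area`; on
  noise-free cells the two routes agree to well under 1% per bin.

## Validation protocols

* Single noise-free cells of both shapes and all three profile kinds
  recover the binned modulus within ~1.5% mean error (the acceptance
  bound is 4%).
* The radius-change baseline (`Y_side = R_A R_B/(R_B - R_A)` per unit
  `P R_A`, `Y_tip` with an extra factor 1/2, both at nu = 0 where
  `Y = 2 K_h`) is evaluated on long-shank cells (98% truncation; the
  method requires a developed cylinder) over a 20–90 degree coverage
  sweep of tip sphere fits.  Side estimates land within ~1.5% of
  `2 K_h`; tip estimates depend on coverage and go negative for the
  rounder chloronema, the baseline's characteristic failure.
* Cohort studies use the standardized protocol of 10 cells with two
  independent triangulations each; error-versus-sample-size curves use
  subsampling without replacement with a Kneedle-style knee (maximum
  normalized distance to the endpoint secant, flat curves flagged).
  Reference maps span ground-truth `(K_side, K_tip)` grids (nonlinear
  profiles off-diagonal, constant on the diagonal) and record the mean
  inferred endpoint ratio, the averaged profile error, and the signed
  and absolute endpoint-ratio errors.
* Desk-scale problem sizes: acceptance runs use 10 repeats of the
  10-cell protocol per map node and two marker draws per noise-free
  condition; the full 100-cell x 100-repeat sweeps remain available
  through the cohort CLI.

## Known limitations

* The shear modulus is not recoverable at the tip (intrinsic isotropy),
  and hence neither is the Poisson ratio; all synthetic defaults assume
  a constant Poisson ratio along the wall.
* Binned comparisons near the apex depend on how much azimuthal marker
  coverage survives the minimum-distance filter; the apex bin of coarse
  triangulations can rest on a handful of faces.
* The medium/high noise magnitudes are presets, not measurements; any
  application to a specific microscope should re-estimate them and use
  the reference maps at the matching level.
* Experimental mode trusts the supplied marker correspondence and
  pixel scale; neither is inferred.
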