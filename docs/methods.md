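# Methods

This note documents the models, algorithms, numerical conventions and design
choices behind `bonefab`, and what the synthetic-data tests do and do not
establish about real micro-CT data.

## Coordinates, units, containers

Volumes are boolean arrays indexed `(z, y, x)`, `z` being the slice axis
(superior–inferior for vertebral specimens whose endplates were aligned
before cropping).  Voxels are isotropic; the edge length is carried in μm.
Morphometric lengths are reported in μm, BS/TV in mm⁻¹, Conn.D. in mm⁻³,
moduli in GPa and, in parallel, normalized to the tissue modulus Et.
Analyses assume axis-aligned cubic volumes of interest (VOIs) cut from the
interior of a specimen; interactive reorientation of raw scans is out of
scope.

## Synthetic volumes

The generator provides analytic phantoms with closed-form properties
(sphere, slab, periodic parallel plates, a cubic rod lattice) and a
trabecular emulator: seeded white noise smoothed with an anisotropic
Gaussian kernel and thresholded at the (1 − BV/TV) quantile of the smoothed
field, which hits the target volume fraction to well under 0.005.  Per-axis
kernel widths are `sigma_voxels · stretch`, with the principal stretch along
the local z-axis; an arbitrary principal direction is obtained by rotating
the field (linear resampling of the periodic field).  All randomness flows
from one integer seed; regeneration is bit-identical.

Defaults and why:

* `sigma_voxels = 2.0` at 80 μm voxels yields a marrow spacing of about
  1.0 mm, matching osteoporotic vertebral cancellous bone; the resulting
  struts (≈ 400 μm) run thicker relative to spacing than real bone, a known
  property of single-scale Gaussian-field microstructures.
* `bvtv_range = (0.082, 0.194)` spans the osteoporotic range; cohort targets
  are spaced evenly across it so the endpoints are always exercised.
* Principal directions are the z-axis tilted by a folded-normal angle of
  scale 6° (vertebral trabeculae align with the endplate normal to within
  roughly 5–10°); stretch ratios 1.8–2.2 produce measured DA near 0.55–0.68.
* Plate-like samples use two stretched axes, rod-like samples one; the
  cohort mixes both.

What the emulator does **not** reproduce: plate-rod network topology
(thresholded Gaussian fields at low volume fraction contain disconnected
islands, so Conn.D. on phantoms can be negative where real bone is positive),
scanner noise and beam hardening, and cortical remnants.  Passing tests on
phantoms therefore validate the *measurement operators* (their geometry,
invariances and parameter recovery), not biological fidelity of any single
index value.

## Morphometry

* **BV/TV** is the exact foreground voxel fraction.
* **BS/TV** triangulates the interface by marching cubes at iso-level 0.5
  after a 1-voxel Gaussian anti-aliasing of the occupancy.  Meshing the raw
  binary field inflates curved and oblique surfaces by up to ~10 %
  (staircase artifact); with the anti-aliasing a radius-20 voxel ball meshes
  to within 0.2 % of 4πr² and axis-aligned planes stay exact.  Faces where
  a structure is clipped by the VOI boundary are not generated (interior
  VOIs expose no cut surface); `closed_boundary=True` caps them instead.
* **Tb.Th. / Tb.Sp.** follow the maximal-inscribed-sphere definition:
  thickness at a voxel is the diameter of the largest sphere containing it
  that fits in the phase.  Sphere radii are Euclidean distance-transform
  values (center to nearest complement-voxel center); painting proceeds in
  descending 0.5-voxel radius bins, each bin realized as a distance
  threshold to its sphere centers.  A 10-voxel slab scores exactly 10; under
  this radius convention an isolated voxel scores 2 (the convention of the
  established trabecular tools; a convention that scores it 1 would misreport
  the slab).  Tb.Sp. is Tb.Th. of the complemented volume (phase duality,
  tested).
* **Conn.D.** = (1 − χ)/TV with χ the Euler characteristic of the bone
  complex at 26-connectivity, equal to the alternating cell count
  V − E + F − C of the closed union of voxel cubes (corner-touching cubes
  share a vertex).  The estimate assumes one connected component and no
  enclosed cavities; the component count is attached so the assumption is
  auditable, and negative values for fragmented inputs are reported as
  computed.
* **EF** (ellipsoid factor) = a/b − b/c of the locally maximal inscribed
  ellipsoid, −1 plate-like to +1 rod-like, 0 for spheres.  Seeds are drawn
  from the medial skeleton and hill-climbed to local maxima of the distance
  transform; from the maximal inscribed sphere, semi-axes along an
  orthonormal triad are grown greedily (0.5-voxel steps, 100 rounds), the
  surface being sampled on 146 directions with a half-voxel containment
  margin; the largest-volume ellipsoid over the axis-aligned triad, a
  local-second-moment-aligned triad and two random triads wins.  Marginal
  growth steps are retried under two fixed rotations of the sample set so a
  single unlucky rounding cannot stall one axis of a symmetric pair.
  `boundary="foreground"` lets ellipsoids continue past the VOI faces, the
  appropriate convention for phantoms of notionally unbounded plates/rods.
* The surface-fraction model BS/TV = K·x·(1 − x) (zero surface at x = 0 and
  x = 1) is fitted in closed form, K = Σwy/Σw² with w = x(1 − x).

## Fabric measurement

Directions are a seeded-rotation Fibonacci lattice on the hemisphere
(antipodal directions are equivalent); 5000 directions is the library
default, and the tests use 600–2000, where doubling the count moves DA by
less than 0.02.  Per direction, parallel test lines with in-plane spacing
`line_spacing` voxels (origins dithered from the seed) are clipped to the
volume and sampled at half-voxel steps.

The bone phase along a ray is the **trilinearly interpolated occupancy
thresholded at 0.5** — the same iso-surface marching cubes extracts.  This
choice is load-bearing: thresholded nearest-voxel lookups cross the jagged
voxel boundary several times when a ray runs obliquely past a flat
interface, which deflates off-axis MIL by ~15 % and drags the fitted
eigenvectors toward the lattice axes (a 12° true tilt measured as 4°).
With interpolation, principal-axis recovery on stretched phantoms is better
than 2° and an isotropic 128³ phantom measures DA ≈ 0.02.  A numba-compiled
kernel executes the marching when numba is importable; the numpy fallback is
semantically identical and their equality is asserted in the tests.

MIL(ω) = total in-volume line length / phase crossings (directions with zero
crossings are dropped and counted).  The tensor fit solves
ωᵀMω = 1/MIL² by linear least squares over the six independent components;
non-positive-definite fits are rejected with advice.  DA = 1 − D₁/D₃ on the
M-eigenvalues; the fabric tensor A = M^(−1/2) shares eigenvectors with M,
its eigenvalues are the MIL ellipsoid radii Dᵢ^(−1/2) sorted descending, and
λ = A-eigenvalues normalized to unit sum.  Near-degenerate eigenvalues
(relative gap < 10⁻⁶) are ordered to maximize |e·ẑ| then |e·ŷ| and flagged.
Orientation angles (α, β, γ) are direction cosines of the principal
eigenvector against x̂, ŷ, ẑ, folded into [0°, 90°].

## Homogenization and the constants profiles

The orthotropic constants in the fabric eigenbasis are polynomial in λ with
nine volume-fraction functions kᵢ = k_ia + k_ib·(BV/TV)^p, p = 1.6,
Et = 15 GPa (see README for the formulas).  Voigt order is
(11, 22, 33, 23, 13, 12); the compliance uses engineering shear strains so
Gᵢ = 1/Sᵢᵢ holds literally, while rotations and the directional modulus use
the tensor convention internally with explicit conversion.  Axes are
permuted so Eₓ′ ≤ E_y′ ≤ E_z′ — z′ is the stiff principal trabecular
direction, the reporting convention of the field.  Positive definiteness is
a recorded flag, never an exception at assembly, so cohort runs complete
and report offending (λ, BV/TV) combinations.

Two constants tables ship as JSON configuration:

* **`printed`** — the published 18-constant table transcribed as printed.
  An independent audit (`audit_positive_definiteness`) shows this set is
  **non-positive-definite over the entire physiological domain**
  (BV/TV ∈ [0.082, 0.194] × the observed fabric range — valid fraction 0.0),
  and no restoration of plausibly lost exponents can repair it: at the
  cohort mean the shear row needs a positive combination of k₇b, k₈b, k₉b,
  but all three printed values are negative.  The table as printed therefore
  cannot generate the published cohort elasticity; it is retained verbatim,
  without silent correction, as the reference transcription.
* **`calibrated`** — the configuration documented to reproduce the reported
  magnitude scale: the k_a column and exponent are kept, and the k_b column
  is re-derived by solving the (linear) nine-constant system against the
  published cohort-mean engineering constants (mean E/Et, G/Et, ν) at the
  cohort-mean volume fraction 0.133 and mean fabric λ = (0.279, 0.304, 0.418).
  With only three distinct λ values the system has a one-dimensional null
  space; the minimum-norm solution is used.  The profile reproduces the nine
  mean constants to < 2 %, including mean E_z′/Et = 47.60·10⁻³, and is
  positive definite across the observed domain at the mean fabric (it can
  fail below BV/TV ≈ 0.07 at extreme anisotropy, outside the observed
  range).  Consistent with the published extrapolation concern, no clamping
  is applied anywhere: extrapolating to BV/TV = 1 exceeds Et.

Cohort analyses that require physical moduli (the worked examples, the
voxel-size sensitivity experiment) use the `calibrated` profile; every
results bundle archives the exact table used.

## Cohort statistics

Power laws y = a·x^b are fitted by nonlinear least squares on the original
scale, initialized from the log-log regression; R² is reported on both
scales (they differ by < 1 % at the 5 % noise level of the tests) and the
p-value is the two-sided test of zero log-log slope.  Descriptive summaries
use the n−1 standard deviation and CV = 100·SD/mean.  No outlier removal is
performed anywhere.

## Voxel-size degradation

`degrade_voxel_size` aggregates factor³ blocks by mean occupancy with the
majority rule (mean ≥ 0.5 → bone; ties to bone); non-divisible axes are
trimmed, never padded.  The rule conserves BV/TV to < 0.02 while structures
remain resolved, and deliberately loses structures thinner than about one
output voxel — the mechanism behind the sensitivity study's stiffness drop.
Two side effects matter for interpretation: at even factors the
tie-to-bone rule biases BV/TV slightly upward (a voxel checkerboard, where
every block is exactly half full, maps to solid bone), so normalized moduli
can tick *up* at factor 2 before the thin-structure loss dominates; the
sensitivity acceptance test therefore evaluates the *trend* (fitted slope of
the seed-averaged normalized modulus against the factor, plus the coarsest
mean below unity), not element-wise monotonicity.  On ten 96³ phantoms the
seed-mean normalized Young's moduli fall to 0.60–0.78 at factor 4, with the
transverse directions losing more than the principal one — the qualitative
pattern reported for real scans degraded 20 → 80 μm.

## Problem sizes in the test suite

Oracle-equivalence tests run on 16³ volumes (exact, line by line);
parameter-recovery tests on 64³–128³ phantoms with 600–2000 MIL directions
at line spacing 2–3 voxels; the sensitivity experiment on ten 96³ phantoms
with 300 directions and no EF.  These sizes were chosen as the smallest at
which the measured quantities are stable against their own sampling noise
(e.g., DA changes < 0.02 when the direction count doubles); the library
defaults remain 5000 directions at 1-voxel spacing.

## Known limitations

* The trabecular emulator is a single-scale Gaussian field: realistic
  spacing and orientation, but too-thick struts, disconnected fragments at
  low BV/TV (negative Conn.D.), and no plate-to-rod transition with density.
* The EF grower explores only four triads per seed and grows greedily; it
  resolves the sphere/rod/plate limits cleanly but individual EF values on
  complex junctions carry sampling noise of order ±0.1.
* MIL values use the crossings normalization; fabric eigenvectors and DA are
  normalization-independent, but absolute MIL magnitudes differ by a factor
  from chord-based (bone-intercept) definitions.
* The printed elasticity-constants table is unusable as printed (see above);
  all absolute moduli therefore rest on the documented calibration, whose
  fidelity is anchored to the published cohort means rather than to the
  original finite-element fit.
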