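# Methods

`hermiteflow` estimates dense displacement fields between consecutive 2D
images or 3D volumes with a differential, multiresolution method whose
data term is built from the coefficients of a local Hermite transform.
This note records the model, the discretization choices, the defaults and
why they were chosen, what the synthetic phantoms emulate, and the known
limitations.

## The local Hermite transform

A volume `L(x)` is analyzed through a bank of separable filters.  Each 1D
kernel is a polynomial of degree `l` multiplied by the squared Gaussian
window `v^2(x) = exp(-x^2/sigma^2)`, sampled on the integer support of an
odd window of `M` voxels; 3D kernels are outer products `D_l(x) D_m(y)
D_n(z)` with total order `l+m+n <= N`.  For `N = 4` in 3D this yields
`(N+1)(N+2)(N+3)/6 = 35` coefficient grids per volume.  The order-0
coefficient is a Gaussian local average of intensity; order-n
coefficients are (discrete analogues of) n-th Gaussian derivatives and
describe edges, ridges and curvature at the window scale.

**Discretization.**  On an `M`-point window, polynomials sampled from the
continuous Hermite family lose their orthogonality (the sampled
even-order kernels acquire a DC leak of order 1e-3).  The bank therefore
orthonormalizes the polynomial family directly against the *sampled*
window weight (a weighted QR factorization of the monomial Vandermonde
matrix).  Consequences, all exercised by tests:

* the order-0 kernel sums to exactly 1 (an intensity-preserving average),
* kernels of order >= 1 respond exactly zero to constants,
* forward + inverse transform reproduces any polynomial of total degree
  <= N exactly on the interior (stride 1),
* the construction requires `N <= M-1`, because monomials above degree
  M-1 are linearly dependent on M samples.  The classical bound
  `N <= 2(M-1)` for the continuous-sampled variant is still validated at
  the API boundary, but the tighter bound is enforced.  The standard
  regime `N = 4, M = 5` sits exactly at the limit.

`sigma` defaults to half the window half-width (`sigma = 1` for `M = 5`),
so +-2 sigma spans the kernel — the receptive-field model of overlapping
Gaussian windows separated by twice the standard deviation.  All
convolutions use mirror boundary padding; the subsampling stride of the
analysis lattice is exposed (default 1: the flow equations are
per-voxel).  Spatial derivatives of coefficient grids are obtained by
*derivative raising*: the derivative of the order-l coefficient along an
axis is the order-(l+1) coefficient scaled by `(l+1) k_{l+1}/k_l`, with
`k_l` the leading coefficient of the l-th discrete orthonormal
polynomial.  This factor is exact on locally polynomial signals and
converges to the continuous `sqrt(2(l+1))/sigma`.

## Orientation and steering

The first-order coefficients approximate the local gradient; its
direction defines two angles (theta in-plane, phi measured from the
z-axis, both quadrant-aware via two-argument arctangents; flat voxels
with zero gradient get the convention value 0 and are flagged through the
energy grid).  Steering rotates each order's coefficient vector onto that
direction.  In the normalized monomial basis `x^a y^b z^c /
sqrt(a!b!c!)`, a spatial rotation acts per order as an orthogonal matrix;
the implementation factors it into two planar rotations (about z by
theta, then about y by phi - pi/2) whose matrix entries are short
polynomials in the angle cosines/sines, evaluated per voxel.  Exact
properties (tested at machine precision): identity at `(theta, phi) =
(0, pi/2)`; per-order energy conservation at every voxel; steering to
the local gradient direction concentrates the entire first-order energy
in the on-axis coefficient.

## The flow functional

With `w = (u, v, w)` the displacement from time t to t+1 and `dw` its
increment at the current linearization point, the energy is

    E = Int  (L0(x,t) - L0(x + w + dw, t+1))^2
         + gamma * Sum_c (l_c(x,t) - l_c(x + w + dw, t+1))^2
         + alpha * |grad(w + dw)|^2  dx

where `L0` is the order-0 coefficient and the sum runs over high-order
coefficient channels (below).  Taylor expansion around the current warp,
with spatial derivatives supplied by derivative raising on the warped
second volume, gives per voxel a d x d linear system `A d = b` coupled to
neighbors through the smoothness Laplacian, discretized in the classical
Horn-Schunck form `alpha (avg_neighbors - center)`.

**Channel selection.**  The high-order term uses one channel per
Cartesian coefficient of orders 1..N-1 — all coefficients whose raised
(order+1) derivative exists; order N enters nothing because its
derivative coefficients do not exist and is truncated.  Two design points
deserve record:

* *Steering invariance.*  Because per-order steering is an orthonormal
  change of basis (with angles frozen from the first volume), the
  weighted normal equations assembled from the full steered set are
  **exactly equal** to those assembled from the Cartesian set.  The
  implementation therefore assembles in the Cartesian frame and a test
  asserts equality against an explicitly steered assembly.
* *Why the full set rather than the on-axis 1D profile.*  Restricting the
  data term to the on-axis steered coefficient of each order was
  implemented and measured first: it stacks near-parallel directional
  constraints whose weighted transverse noise overwhelms the smoothness
  term (translation endpoint error ~3.9 voxels at defaults, growing with
  each warp).  The full per-order set constrains all directions and is
  stable; it also keeps the steered and Cartesian formulations
  numerically identical, which pins the behavior to a provable property
  rather than ambiguous index bookkeeping.

`gamma` is divided by the number of active channels (`normalize_gamma`,
default on) so its scale does not depend on N.

**Intensity scale.**  The input pair is rescaled internally to peak 255
before estimation.  The tuned weights `alpha >= 10`, `gamma >= 100` are
only meaningful relative to a contrast scale; 8-bit peak is the scale of
the Horn-Schunck literature and of the standard 2D benchmark images.
Flow output is in voxels and invariant to common intensity scaling.

**Solver.**  The per-voxel d x d matrices (data term plus alpha on the
diagonal) are inverted once per warp in closed form; the neighbor
coupling is then iterated — red/black Gauss-Seidel by default, plain
Jacobi optionally — until `iterations` sweeps or the mean update falls
below `solver_tolerance`.  Near-singular voxel systems (possible only
for degenerate data with alpha ~ 0) receive a tiny diagonal jitter and a
warning.  Per warp pass, increments are clamped to `max_increment`
(default 1 voxel): the Taylor linearization is only valid for small
residual motion, and unclamped outlier updates were observed to
self-amplify across warps.  Coarse-to-fine: a Gaussian pyramid
(low-pass, decimate by 2; clipped so the coarsest level keeps >= 8
samples per axis), `warps_per_level = 3` re-linearizations per level,
flow upsampled by linear interpolation and scaled by the magnification.

**Defaults** (the tuned regime): `alpha = 10`, `gamma = 100`, `N = 4`,
window `5`, `levels = 5`, `iterations = 50`, `tolerance = 1e-4`.
`baseline_mode` (or `gamma = 0`) drops the high-order term, leaving a
multiresolution Horn-Schunck used as the comparison baseline.

## Validation metrics

Without ground-truth motion, flow quality is measured by forward
reconstruction: predict the t+1 volume by warping the t volume with the
negated flow and compare:

* `IE = sqrt(mean (L(t+1) - L_rec)^2)` (RMS, intensity units),
* `NE = sqrt(mean (L(t+1) - L_rec)^2 / (|grad L(t+1)|^2 + eps))`,
  `eps = 1` by default; gradients by central differences with mirrored
  edges.

Errors are computed on the stored intensity scale by default; an
`intensity_scale` argument divides both volumes first.  The experiment
protocol (tests, acceptance script) passes the sequence's peak intensity,
reporting unit-scale errors — the convention under which the tuned
regime's quality bar `NE < 0.1` and the reported IE magnitudes of
12-bit cardiac data are coherent.  Masked evaluation (e.g. a segmented
left-ventricle mask, nonzero = inside) restricts the voxel count.

## Synthetic phantoms

The phantoms define the study conditions; their defaults were fixed once:

* **Intensity scale**: 12-bit-like (CT emulation): ellipsoidal shell
  ~2000, additive band-limited Gaussian texture of contrast (std) 600,
  correlation length 4 voxels, background ~0.  The noise preset
  `sigma in {0, 5, 10, 15, 20, 30}` lives on this stored scale — mild
  acquisition noise, the reading consistent with reported cardiac IE
  values remaining small.
* **Translation**: rigid shifts of the periodic texture applied
  spectrally (FFT phase shift), which is exact for band-limited periodic
  fields; linear interpolation would low-pass half-voxel shifts and
  corrupt the ground truth by construction (measured: +0.09 voxels of
  apparent endpoint error from the phantom alone).  Ground-truth flow is
  exactly constant.
* **Rotation**: in-plane rigid rotation about the center; each frame is
  resampled from the previous one with the estimator's own linear
  interpolator, using the exact inverse rotation, so sequence and ground
  truth are consistent.
* **Beating ellipsoid**: a shell at 30% of the grid extent whose radius
  follows a piecewise-cosine schedule with end-contraction at 30% of the
  cycle and end-dilation (amplitude ratio 0.25) at 70%; default
  amplitude 2 voxels peak contraction displacement, shape 48^3, 10
  phases (0%..90%).  The radial displacement is tapered smoothly to zero
  at the volume faces so edge-clamped warping stays self-consistent;
  frames are generated by warping the previous frame with the negated
  ground-truth flow (the same interpolator the estimator uses).  For
  non-rigid fields this backward generation matches the forward ground
  truth to first order; the residual is O(|w| |grad w|), about 0.1 voxel
  at the default amplitude.

What passing phantom tests do *not* show about real data: the phantoms
have no contrast variation between frames, no CT reconstruction
artifacts or correlated noise, no through-plane anisotropy, no topology
changes, and far smaller volumes than clinical acquisitions.  They test
the estimator's numerics, not its clinical adequacy.

Endpoint errors against ground truth are averaged over the interior,
excluding a margin equal to the analysis window (4 voxels) where the
windowed transform needs boundary extrapolation.

## Problem sizes

The packaged experiments use 64^3 translation phantoms, the 48^3/10-phase
ellipsoid, and 24^3 fixtures for solver-identity checks — sizes at which
every experiment reruns from scratch in minutes on one CPU while leaving
all observed effects (pyramid necessity, baseline gap, noise monotonicity)
well resolved.

## Known limitations

* Quadratic penalties only; no robust data term, no median filtering of
  intermediate flows (kept out of scope deliberately).
* Orientation is frozen per level from the first volume; spatial
  variation of the steering angles is neglected in the derivative
  raising (standard frozen-frame approximation).
* The discrete derivative-raising factor is exact only on locally
  polynomial signals; against central finite differences it agrees to a
  few percent on smooth fields.
* `N > M-1` banks are rejected rather than falling back to non-orthogonal
  sampled kernels.
* 2D benchmark reproduction requires the external benchmark images; the
  `benchmark` CLI command consumes a local directory and is exercised in
  tests only through self-constructed fixtures.
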