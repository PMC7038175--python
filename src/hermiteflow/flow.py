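"""Hermite optical flow (HOF): multiresolution warping-based estimation.

The data term extends Horn-Schunck brightness constancy: the order-0
Hermite coefficient (a Gaussian local average of intensity) provides the
classical constraint, and the on-axis steered coefficients of orders
1..N-1 add oriented high-order structure, weighted by gamma.  A quadratic
smoothness term weighted by alpha propagates flow into flat regions.

Minimizing the linearized functional gives one d x d linear system per
voxel coupled to its neighbors through the smoothness Laplacian; the
solver iterates per-voxel solves with neighbor-average coupling
(Gauss-Seidel red/black by default, Jacobi optionally).  Large
displacements are handled coarse-to-fine: flow estimated on a decimated
level warps the second volume at the next finer level so only a small
residual motion remains to be linearized.

Works in 2D (HOF2D) and 3D (HOF3D); ``baseline_mode`` drops the
high-order term (gamma = 0), leaving a multiresolution Horn-Schunck.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .hermite import (
    HermiteCoefficients,
    as_array,
    build_filter_bank,
    forward_transform,
)
logger = logging.getLogger("hermiteflow")

__all__ = [
    "FlowParams",
    "FlowField",
    "LinearSystem",
    "build_pyramid",
    "warp",
    "temporal_differences",
    "assemble_system",
    "solve_increment",
    "estimate_flow",
]

#: smallest per-axis extent allowed at the coarsest pyramid level
MIN_COARSE_EXTENT = 8


@dataclass
class FlowParams:
    """Tunable parameters of the estimator.

    Defaults are the tuned regime for cardiac volumes: alpha=10, gamma=100,
    N=4 with a 5-voxel window, 5 pyramid levels, 50 solver iterations.
    ``gamma`` is divided by the number of active steered channels
    (``normalize_gamma``) so its scale is insensitive to N.
    """

    alpha: float = 10.0
    gamma: float = 100.0
    order_max: int = 4
    window_size: int = 5
    sigma: Optional[float] = None
    levels: int = 5
    iterations: int = 50
    warps_per_level: int = 3
    solver_tolerance: float = 1e-4
    solver: str = "gauss_seidel"
    max_increment: float = 1.0
    baseline_mode: bool = False
    normalize_gamma: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.warps_per_level < 1:
            raise ValueError("warps_per_level must be >= 1")
        if self.max_increment <= 0:
            raise ValueError("max_increment must be > 0")
        if self.solver not in ("gauss_seidel", "jacobi"):
            raise ValueError("solver must be 'gauss_seidel' or 'jacobi'")

    @property
    def effective_gamma(self) -> float:
        if self.baseline_mode:
            return 0.0
        return self.gamma


@dataclass
class FlowField:
    """Dense displacement field in voxel units.

    ``components[i]`` is the displacement along axis i; a position x at
    time t corresponds to x + w(x) at time t+1.  ``increments`` holds the
    latest per-level update (du, dv, dw).
    """

    components: Tuple[np.ndarray, ...]
    increments: Optional[Tuple[np.ndarray, ...]] = None

    @property
    def ndim(self) -> int:
        return len(self.components)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.components[0].shape

    @property
    def u(self) -> np.ndarray:
        return self.components[0]

    @property
    def v(self) -> np.ndarray:
        return self.components[1]

    @property
    def w(self) -> np.ndarray:
        if len(self.components) < 3:
            raise AttributeError("2D flow has no w component")
        return self.components[2]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(sum(c**2 for c in self.components))

    @classmethod
    def zeros(cls, shape: Tuple[int, ...], ndim: Optional[int] = None) -> "FlowField":
        d = ndim if ndim is not None else len(shape)
        return cls(tuple(np.zeros(shape) for _ in range(d)))


# ---------------------------------------------------------------------------
# pyramid and warping


def build_pyramid(volume, levels: int) -> List[np.ndarray]:
    """Gaussian pyramid: each level low-pass filtered and decimated by 2.

    Levels are clipped so the coarsest level keeps at least
    ``MIN_COARSE_EXTENT`` samples per axis (a warning is logged).
    Level 0 is the input.
    """
    data = as_array(volume)
    pyramid = [data]
    for k in range(1, levels):
        prev = pyramid[-1]
        if min(prev.shape) < 2 * MIN_COARSE_EXTENT:
            logger.warning(
                "pyramid clipped to %d levels (coarse shape %s)",
                len(pyramid),
                prev.shape,
            )
            break
        smoothed = ndimage.gaussian_filter(prev, sigma=1.0, mode="nearest")
        pyramid.append(smoothed[tuple(slice(None, None, 2) for _ in prev.shape)])
    return pyramid


def warp(volume, flow: FlowField) -> np.ndarray:
    """Backward warping: output at x samples the input at x + w(x).

    Linear (bi-/trilinear) interpolation, edge clamping outside the domain.
    """
    data = as_array(volume)
    if flow.shape != data.shape:
        raise ValueError("flow shape does not match volume shape")
    grids = np.meshgrid(
        *[np.arange(s, dtype=np.float64) for s in data.shape], indexing="ij"
    )
    coords = [g + c for g, c in zip(grids, flow.components)]
    return ndimage.map_coordinates(data, coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# constraint channels and the per-voxel linear system


@dataclass
class ConstraintChannels:
    """Per-channel temporal differences and spatial derivative grids.

    Each channel contributes a linearized constancy constraint
    ``diff + grad . d = 0`` with weight ``weight``.
    """

    diffs: List[np.ndarray] = field(default_factory=list)
    grads: List[Tuple[np.ndarray, ...]] = field(default_factory=list)
    weights: List[float] = field(default_factory=list)

    def append(self, diff, grad, weight) -> None:
        self.diffs.append(diff)
        self.grads.append(grad)
        self.weights.append(float(weight))


def _raised_gradients(
    coeffs: HermiteCoefficients, order: int
) -> Tuple[Dict[Tuple[int, ...], np.ndarray], ...]:
    """Spatial derivative stacks of the order-n coefficients, obtained from
    the order-(n+1) coefficients via the derivative-raising factors."""
    bank = coeffs.bank
    factors = bank.raise_factors
    ndim = coeffs.ndim
    out = []
    for axis in range(ndim):
        stack: Dict[Tuple[int, ...], np.ndarray] = {}
        for idx, _ in coeffs.order(order).items():
            raised = list(idx)
            raised[axis] += 1
            stack[idx] = factors[idx[axis]] * coeffs[tuple(raised)]
        out.append(stack)
    return tuple(out)


def temporal_differences(
    coeffs_t: HermiteCoefficients,
    coeffs_t1_warped: HermiteCoefficients,
    params: FlowParams,
) -> ConstraintChannels:
    """Build the constraint channels from the two coefficient sets.

    Channel 0 is the order-0 (brightness) coefficient with its gradient
    taken from the first-order coefficients of the warped second volume.
    The high-order term contributes one channel per coefficient of orders
    1..N-1 — the orders whose raised (order+1) derivative coefficients
    exist; order N only lacks its derivative and is truncated.

    The channels are assembled in the Cartesian frame: steering is an
    orthonormal per-order change of basis (with the orientation frozen
    from the first volume), under which the weighted normal equations are
    exactly invariant, so the system equals the one assembled from
    steered coefficients.  Gamma is split evenly over the channels when
    ``normalize_gamma`` is set.
    """
    if coeffs_t.grid_shape != coeffs_t1_warped.grid_shape:
        raise ValueError("coefficient sets are on different grids")
    ndim = coeffs_t.ndim
    n_max = coeffs_t.order_max
    ch = ConstraintChannels()

    dc = (0,) * ndim
    diff0 = coeffs_t1_warped[dc] - coeffs_t[dc]
    grad0_stacks = _raised_gradients(coeffs_t1_warped, 0)
    grad0 = tuple(stack[dc] for stack in grad0_stacks)
    ch.append(diff0, grad0, 1.0)

    gamma = params.effective_gamma
    if gamma > 0.0 and n_max >= 2:
        orders = list(range(1, n_max))
        n_channels = sum(len(coeffs_t.order(n)) for n in orders)
        w = gamma / n_channels if params.normalize_gamma else gamma
        for n in orders:
            stacks = _raised_gradients(coeffs_t1_warped, n)
            for q in sorted(coeffs_t.order(n)):
                ch.append(
                    coeffs_t1_warped[q] - coeffs_t[q],
                    tuple(stack[q] for stack in stacks),
                    w,
                )
    elif gamma > 0.0:
        logger.info(
            "order_max=%d leaves no high-order channel with a raised "
            "derivative; data term reduces to the brightness constraint",
            n_max,
        )
    return ch


@dataclass
class LinearSystem:
    """Per-voxel normal equations ``A d = b_static + alpha * avg(d)``.

    ``A`` has shape (d, d, *grid) and contains the symmetric data term
    plus alpha on the diagonal; ``b_static`` is the right-hand side at
    zero increment (data residual plus the neighbor coupling of the
    current flow).  Named accessors follow the row-major 3x3 layout.
    """

    A: np.ndarray
    b_static: np.ndarray
    alpha: float

    @property
    def ndim(self) -> int:
        return self.A.shape[0]

    def __getattr__(self, name: str):
        if name.startswith("A") and name[1:].isdigit():
            k = int(name[1:]) - 1
            d = self.A.shape[0]
            if 0 <= k < d * d:
                return self.A[k // d, k % d]
        if name.startswith("b") and name[1:].isdigit():
            k = int(name[1:]) - 1
            if 0 <= k < self.b_static.shape[0]:
                return self.b_static[k]
        raise AttributeError(name)


def _neighbor_average(arr: np.ndarray) -> np.ndarray:
    """Mean of the 2*d axis neighbors (4 in 2D, 6 in 3D), edges replicated."""
    acc = np.zeros_like(arr)
    for axis in range(arr.ndim):
        acc += ndimage.correlate1d(arr, [0.5, 0.0, 0.5], axis=axis, mode="nearest")
    return acc / arr.ndim


def assemble_system(
    channels: ConstraintChannels, flow: FlowField, params: FlowParams
) -> LinearSystem:
    """Normal equations of the linearized functional.

    ``A[i][j] = sum_ch w * g_i * g_j`` (+ alpha on the diagonal);
    ``b_static[i] = -sum_ch w * diff * g_i + alpha * (avg(w_i) - w_i)``.
    With gamma = 0 this is the classical Horn-Schunck system on the
    order-0 channel.
    """
    d = flow.ndim
    grid = flow.shape
    A = np.zeros((d, d) + grid)
    b = np.zeros((d,) + grid)
    for diff, grad, w in zip(channels.diffs, channels.grads, channels.weights):
        for i in range(d):
            b[i] -= w * diff * grad[i]
            for j in range(i, d):
                A[i, j] += w * grad[i] * grad[j]
    for i in range(d):
        for j in range(i):
            A[i, j] = A[j, i]
        A[i, i] += params.alpha
        b[i] += params.alpha * (_neighbor_average(flow.components[i]) - flow.components[i])
    return LinearSystem(A=A, b_static=b, alpha=params.alpha)


def _per_voxel_inverse(A: np.ndarray) -> np.ndarray:
    """Invert the stack of d x d matrices; near-singular voxels get a tiny
    diagonal jitter (can only happen for degenerate data with alpha ~ 0)."""
    d = A.shape[0]
    mats = np.moveaxis(A.reshape(d, d, -1), -1, 0)
    det = np.linalg.det(mats)
    bad = np.abs(det) < 1e-12
    if np.any(bad):
        logger.warning(
            "%d near-singular voxel systems regularized with diagonal jitter",
            int(bad.sum()),
        )
        mats = mats.copy()
        mats[bad] += 1e-9 * np.eye(d)
    inv = np.linalg.inv(mats)
    return np.moveaxis(inv, 0, -1).reshape(A.shape)


def _checkerboard(shape: Tuple[int, ...]) -> np.ndarray:
    idx = np.zeros(shape, dtype=np.int64)
    for axis, s in enumerate(shape):
        view = [None] * len(shape)
        view[axis] = slice(None)
        idx = idx + np.arange(s)[tuple(view)]
    return (idx % 2).astype(bool)


def solve_increment(
    system: LinearSystem,
    params: FlowParams,
    init: Optional[Tuple[np.ndarray, ...]] = None,
) -> Tuple[np.ndarray, ...]:
    """Iterate per-voxel solves with neighbor-average coupling.

    Runs until ``params.iterations`` sweeps or until the mean update
    magnitude drops below ``params.solver_tolerance``.
    """
    d = system.ndim
    grid = system.b_static.shape[1:]
    inv = _per_voxel_inverse(system.A)
    incr = (
        np.stack(init)
        if init is not None
        else np.zeros((d,) + grid)
    )
    alpha = system.alpha
    red = _checkerboard(grid)
    colors = (red, ~red) if params.solver == "gauss_seidel" else (None,)

    for _ in range(params.iterations):
        prev = incr.copy()
        for color in colors:
            rhs = system.b_static + alpha * np.stack(
                [_neighbor_average(incr[i]) for i in range(d)]
            )
            new = np.einsum("ij...,j...->i...", inv, rhs)
            if color is None:
                incr = new
            else:
                incr[:, color] = new[:, color]
        delta = float(np.mean(np.abs(incr - prev)))
        if delta < params.solver_tolerance:
            break
    return tuple(incr[i] for i in range(d))


# ---------------------------------------------------------------------------
# coarse-to-fine driver


def _upsample_flow(flow: FlowField, target_shape: Tuple[int, ...]) -> FlowField:
    """Linear interpolation of each component to the finer grid, with the
    displacement values rescaled by the per-axis magnification."""
    comps = []
    factors = [t / c for t, c in zip(target_shape, flow.shape)]
    for i, comp in enumerate(flow.components):
        up = ndimage.zoom(comp, factors, order=1, mode="nearest", grid_mode=True)
        comps.append(up * factors[i])
    return FlowField(tuple(comps))


def _functional_energy(
    channels: ConstraintChannels,
    flow: FlowField,
    incr: Sequence[np.ndarray],
    params: FlowParams,
) -> float:
    """Value of the (linearized) energy functional, for per-level logging."""
    e = 0.0
    for diff, grad, w in zip(channels.diffs, channels.grads, channels.weights):
        resid = diff + sum(g * di for g, di in zip(grad, incr))
        e += w * float(np.sum(resid**2))
    for comp, di in zip(flow.components, incr):
        total = comp + di
        e += params.alpha * float(
            sum(np.sum(g**2) for g in np.gradient(total))
        )
    return e


def estimate_flow(volume_t, volume_t1, params: Optional[FlowParams] = None) -> FlowField:
    """Estimate the dense displacement field from volume_t to volume_t1.

    Coarse-to-fine: per level the second volume is warped by the current
    flow, Hermite coefficients of both are computed, the linearized system
    is assembled (equal, by per-order orthonormality, to the one built
    from coefficients steered to the first volume's orientation) and
    solved for an increment; the loop re-warps ``warps_per_level`` times
    before the flow is upsampled to the next finer level.
    """
    params = params or FlowParams()
    a = as_array(volume_t)
    b = as_array(volume_t1)
    if a.shape != b.shape:
        raise ValueError("volumes must share a common shape")
    if a.ndim not in (2, 3):
        raise ValueError("only 2D and 3D volumes are supported")
    # normalize the pair to an 8-bit-like peak (255) so alpha and gamma
    # refer to the standard contrast scale of the Horn-Schunck literature,
    # regardless of the stored range (12-bit CT, unit-scale or 8-bit data
    # then all behave identically)
    scale = max(float(np.abs(a).max()), float(np.abs(b).max()))
    if scale > 0:
        a = a * (255.0 / scale)
        b = b * (255.0 / scale)

    bank = build_filter_bank(
        params.order_max, params.window_size, params.sigma, ndim=a.ndim
    )
    pyr_a = build_pyramid(a, params.levels)
    pyr_b = build_pyramid(b, params.levels)
    n_levels = min(len(pyr_a), len(pyr_b))

    flow = FlowField.zeros(pyr_a[n_levels - 1].shape, ndim=a.ndim)
    last_incr: Tuple[np.ndarray, ...] = flow.components
    for level in range(n_levels - 1, -1, -1):
        lvl_a, lvl_b = pyr_a[level], pyr_b[level]
        if flow.shape != lvl_a.shape:
            flow = _upsample_flow(flow, lvl_a.shape)
        coeffs_t = forward_transform(lvl_a, bank)
        channels = None
        for _ in range(params.warps_per_level):
            warped = warp(lvl_b, flow)
            coeffs_w = forward_transform(warped, bank)
            channels = temporal_differences(coeffs_t, coeffs_w, params)
            system = assemble_system(channels, flow, params)
            incr = solve_increment(system, params)
            # the Taylor linearization only holds for small residual
            # motion; clamp each update so one warp pass never moves a
            # voxel further than the validity range (coarse-to-fine
            # handles large displacements)
            lim = params.max_increment
            incr = tuple(np.clip(di, -lim, lim) for di in incr)
            flow = FlowField(
                tuple(c + di for c, di in zip(flow.components, incr)),
                increments=incr,
            )
            last_incr = incr
        if logger.isEnabledFor(logging.DEBUG) and channels is not None:
            logger.debug(
                "level %d (shape %s): energy %.6g",
                level,
                lvl_a.shape,
                _functional_energy(channels, flow, [np.zeros_like(c) for c in last_incr], params),
            )
    if not all(np.isfinite(c).all() for c in flow.components):
        raise FloatingPointError("flow field contains non-finite values")
    return flow


def horn_schunck_baseline(volume_t, volume_t1, params: Optional[FlowParams] = None) -> FlowField:
    """Multiresolution Horn-Schunck: the same pyramid/warping scaffold with
    the high-order term dropped (gamma = 0)."""
    params = params or FlowParams()
    return estimate_flow(volume_t, volume_t1, replace(params, baseline_mode=True))
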