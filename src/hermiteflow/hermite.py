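"""Discrete N-dimensional Hermite transform.

A signal is analyzed through a bank of Gaussian-derivative-like filters:
each 1D kernel is a polynomial of degree ``l`` times the squared Gaussian
window ``v^2(x) = exp(-x^2/sigma^2)``, sampled on the integer support
``[-r, r]`` of an odd window of ``M = 2r + 1`` voxels.  The polynomial
family is orthonormalized against the *sampled* window weight, so the
discrete bank inherits the defining properties of the continuous
transform exactly:

* the order-0 kernel is an intensity-preserving local average (DC gain 1),
* kernels of order >= 1 have exactly zero response to constants,
* analysis followed by synthesis reproduces any polynomial of total
  degree <= N on the interior at machine precision (for stride 1).

For well-sampled windows the kernels converge to the classical Hermite
analysis filters ``D_l(x) ∝ H_l(x/sigma) exp(-x^2/sigma^2)`` with ``H_l``
the (physicists') Hermite polynomials.

Coordinate convention used throughout the package: arrays are indexed
``(x, y, z) = (axis 0, axis 1, axis 2)``, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from numpy.polynomial import hermite as _herm
from scipy import ndimage

__all__ = [
    "Volume",
    "GaussianWindow",
    "HermiteFilterBank",
    "HermiteCoefficients",
    "hermite_polynomial",
    "build_filter_bank",
    "forward_transform",
    "inverse_transform",
    "as_array",
    "as_volume",
]

#: boundary mode used for every analysis convolution (mirror padding,
#: avoids spurious gradients at volume faces)
BOUNDARY_MODE = "mirror"


# ---------------------------------------------------------------------------
# containers


@dataclass
class Volume:
    """A scalar intensity grid (2D or 3D) with voxel spacing.

    ``data`` is stored as float64; ``spacing`` is the physical voxel size
    per axis (index-space algorithms ignore it, writers propagate it).
    """

    data: np.ndarray
    spacing: Tuple[float, ...] = None  # type: ignore[assignment]
    time_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.data.ndim}-D volume"
            )

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim


def as_array(volume) -> np.ndarray:
    """Accept a :class:`Volume` or a bare array, return float64 ndarray."""
    if isinstance(volume, Volume):
        return volume.data
    return np.asarray(volume, dtype=np.float64)


def as_volume(volume, spacing=None) -> Volume:
    if isinstance(volume, Volume):
        return volume
    return Volume(np.asarray(volume, dtype=np.float64), spacing=spacing)


@dataclass(frozen=True)
class GaussianWindow:
    """Isotropic Gaussian analysis window.

    ``sigma`` is the standard deviation in voxel units; ``support_radius``
    the integer half-width r of the discrete kernel (window size 2r+1).
    """

    sigma: float
    support_radius: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.support_radius < 1:
            raise ValueError("support_radius must be >= 1")

    @property
    def size(self) -> int:
        return 2 * self.support_radius + 1

    def sampled_squared(self) -> np.ndarray:
        """v^2 sampled on the integer support (strictly positive, symmetric)."""
        x = np.arange(-self.support_radius, self.support_radius + 1)
        return np.exp(-(x**2) / self.sigma**2)


# ---------------------------------------------------------------------------
# 1D polynomial machinery


def hermite_polynomial(l: int, x, sigma: float = 1.0) -> np.ndarray:
    """Evaluate the physicists' Hermite polynomial H_l(x/sigma) pointwise.

    Satisfies the recurrence ``H_{l+1}(t) = 2 t H_l(t) - 2 l H_{l-1}(t)``
    with H_0 = 1, H_1(t) = 2t (Rodrigues construction).
    """
    if l < 0:
        raise ValueError("polynomial order must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = np.asarray(x, dtype=np.float64) / sigma
    coeffs = np.zeros(l + 1)
    coeffs[l] = 1.0
    return _herm.hermval(t, coeffs)


def _discrete_orthonormal_polynomials(
    order_max: int, window: GaussianWindow
) -> Tuple[np.ndarray, np.ndarray]:
    """Polynomials orthonormal under the sampled squared-Gaussian weight.

    Returns ``(values, leading)`` where ``values[:, l]`` are the samples of
    Q_l on the integer support (sum_i Q_j(i) Q_k(i) w(i) = delta_jk) and
    ``leading[l]`` is the coefficient of ``i**l`` in Q_l.  Built by a
    weighted QR factorization of the monomial Vandermonde matrix, which is
    numerically stable for the small orders used here.
    """
    r = window.support_radius
    nodes = np.arange(-r, r + 1, dtype=np.float64)
    w = window.sampled_squared()
    # scale nodes by sigma for conditioning; rescale leading coeffs after
    t = nodes / window.sigma
    vand = np.vander(t, order_max + 1, increasing=True)
    q, rmat = np.linalg.qr(np.sqrt(w)[:, None] * vand)
    sign = np.sign(np.diag(rmat))
    sign[sign == 0] = 1.0
    q = q * sign
    rmat = sign[:, None] * rmat
    values = q / np.sqrt(w)[:, None]
    inv_diag = 1.0 / np.diag(rmat)
    leading = inv_diag / window.sigma ** np.arange(order_max + 1)
    return values, leading


# ---------------------------------------------------------------------------
# filter bank


@dataclass
class HermiteFilterBank:
    """Separable analysis filter bank up to total order N.

    ``filters`` maps each index tuple (order per axis) to its full N-D
    kernel; every kernel factorizes exactly into the 1D kernels stored in
    ``kernels_1d`` (outer products).  ``raise_factors[l]`` converts the
    order-(l+1) coefficient into the spatial derivative of the order-l
    coefficient (exact on local polynomials of degree l+1).
    """

    order_max: int
    window: GaussianWindow
    ndim: int
    kernels_1d: np.ndarray  # (window_size, order_max+1)
    synthesis_1d: np.ndarray  # (window_size, order_max+1)
    leading: np.ndarray  # (order_max+1,)
    filters: Dict[Tuple[int, ...], np.ndarray] = field(default_factory=dict)

    @property
    def window_size(self) -> int:
        return self.window.size

    @property
    def sigma(self) -> float:
        return self.window.sigma

    @property
    def raise_factors(self) -> np.ndarray:
        l = np.arange(self.order_max)
        return (l + 1) * self.leading[1:] / self.leading[:-1]

    def indices(self):
        """All index tuples with total order <= N, in lexicographic order."""
        return sorted(self.filters.keys())

    def kernel_1d(self, l: int) -> np.ndarray:
        return self.kernels_1d[:, l]


def _index_tuples(order_max: int, ndim: int):
    if ndim == 1:
        return [(n,) for n in range(order_max + 1)]
    if ndim == 2:
        return [
            (a, n - a) for n in range(order_max + 1) for a in range(n, -1, -1)
        ]
    return [
        (a, b, n - a - b)
        for n in range(order_max + 1)
        for a in range(n, -1, -1)
        for b in range(n - a, -1, -1)
    ]


def build_filter_bank(
    order_max: int,
    window_size: int,
    sigma: Optional[float] = None,
    ndim: int = 3,
) -> HermiteFilterBank:
    """Construct the separable Hermite analysis bank.

    ``sigma`` defaults to half the window half-width (sigma=1 for a 5-voxel
    window), so +-2 sigma spans the kernel, matching the overlapping
    receptive-field model of Gaussian windows separated by twice the
    standard deviation.
    """
    if ndim not in (1, 2, 3):
        raise ValueError("ndim must be 1, 2 or 3")
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 3")
    if order_max < 0:
        raise ValueError("order_max must be >= 0")
    if order_max > 2 * (window_size - 1):
        raise ValueError(
            f"order_max={order_max} violates N <= 2*(M-1) for window "
            f"size M={window_size}"
        )
    if order_max > window_size - 1:
        # monomials above degree M-1 are linearly dependent on M samples;
        # the orthonormal discrete bank therefore needs N <= M-1
        raise ValueError(
            f"order_max={order_max} exceeds window_size-1={window_size - 1}; "
            "the discrete bank requires N <= M-1"
        )
    r = (window_size - 1) // 2
    if sigma is None:
        sigma = r / 2.0
    window = GaussianWindow(sigma=float(sigma), support_radius=r)

    values, leading = _discrete_orthonormal_polynomials(order_max, window)
    w = window.sampled_squared()
    z = w.sum()
    # analysis: correlate with Q_l * w / sqrt(Z)  (DC gain of order 0 == 1)
    kernels = values * w[:, None] / np.sqrt(z)
    # synthesis: convolve lattice coefficients with sqrt(Z) * Q_l * w and
    # normalize by the accumulated window weight (Eq-10-style interpolation)
    synthesis = values * w[:, None] * np.sqrt(z)

    bank = HermiteFilterBank(
        order_max=order_max,
        window=window,
        ndim=ndim,
        kernels_1d=kernels,
        synthesis_1d=synthesis,
        leading=leading,
    )
    for idx in _index_tuples(order_max, ndim):
        k = kernels[:, idx[0]]
        for ax_order in idx[1:]:
            k = np.multiply.outer(k, kernels[:, ax_order])
        bank.filters[idx] = k
    return bank


# ---------------------------------------------------------------------------
# forward / inverse transform


@dataclass
class HermiteCoefficients:
    """Cartesian Hermite coefficients on the (possibly subsampled) lattice S."""

    coeffs: Dict[Tuple[int, ...], np.ndarray]
    order_max: int
    sigma: float
    stride: int
    source_shape: Tuple[int, ...]
    window_size: int
    bank: Optional[HermiteFilterBank] = None

    @property
    def ndim(self) -> int:
        return len(self.source_shape)

    @property
    def grid_shape(self) -> Tuple[int, ...]:
        return next(iter(self.coeffs.values())).shape

    def order(self, n: int) -> Dict[Tuple[int, ...], np.ndarray]:
        """Coefficients of total order exactly n."""
        return {k: v for k, v in self.coeffs.items() if sum(k) == n}

    def __getitem__(self, idx: Tuple[int, ...]) -> np.ndarray:
        return self.coeffs[idx]


def forward_transform(
    volume, bank: HermiteFilterBank, stride: int = 1
) -> HermiteCoefficients:
    """Analyze a volume: correlate with every bank filter, subsample by stride.

    Separability is exploited (one 1D pass per axis, shared between indices
    with a common prefix); the result equals the direct N-D convolution.
    """
    data = as_array(volume)
    if data.ndim != bank.ndim:
        raise ValueError(
            f"volume is {data.ndim}-D but the bank was built for "
            f"{bank.ndim}-D signals"
        )
    if stride < 1 or any(stride > s for s in data.shape):
        raise ValueError("stride must be >= 1 and no larger than any axis")

    coeffs: Dict[Tuple[int, ...], np.ndarray] = {}
    sl = tuple(slice(None, None, stride) for _ in range(data.ndim))
    # axis-0 passes shared across all indices with the same first order
    cache0 = {
        a: ndimage.correlate1d(data, bank.kernel_1d(a), axis=0, mode=BOUNDARY_MODE)
        for a in range(bank.order_max + 1)
    }
    if data.ndim == 1:
        for (a,) in bank.indices():
            coeffs[(a,)] = cache0[a][sl].copy()
    elif data.ndim == 2:
        for a in range(bank.order_max + 1):
            for b in range(bank.order_max + 1 - a):
                arr = ndimage.correlate1d(
                    cache0[a], bank.kernel_1d(b), axis=1, mode=BOUNDARY_MODE
                )
                coeffs[(a, b)] = arr[sl].copy()
    else:
        for a in range(bank.order_max + 1):
            for b in range(bank.order_max + 1 - a):
                tmp = ndimage.correlate1d(
                    cache0[a], bank.kernel_1d(b), axis=1, mode=BOUNDARY_MODE
                )
                for c in range(bank.order_max + 1 - a - b):
                    arr = ndimage.correlate1d(
                        tmp, bank.kernel_1d(c), axis=2, mode=BOUNDARY_MODE
                    )
                    coeffs[(a, b, c)] = arr[sl].copy()
    return HermiteCoefficients(
        coeffs=coeffs,
        order_max=bank.order_max,
        sigma=bank.sigma,
        stride=stride,
        source_shape=data.shape,
        window_size=bank.window_size,
        bank=bank,
    )


def inverse_transform(coeffs: HermiteCoefficients) -> Volume:
    """Reconstruct the signal by interpolating coefficients with the
    synthesis filters (windowed-polynomial interpolation, normalized by the
    accumulated window weight over the lattice)."""
    bank = coeffs.bank
    if bank is None:
        raise ValueError("coefficients carry no filter bank; cannot invert")
    expected = set(map(tuple, _index_tuples(coeffs.order_max, coeffs.ndim)))
    if set(coeffs.coeffs.keys()) != expected:
        missing = expected - set(coeffs.coeffs.keys())
        raise ValueError(f"coefficient set incomplete, missing indices {missing}")

    shape = coeffs.source_shape
    stride = coeffs.stride
    acc = np.zeros(shape, dtype=np.float64)

    def upsample(grid: np.ndarray) -> np.ndarray:
        full = np.zeros(shape, dtype=np.float64)
        full[tuple(slice(None, None, stride) for _ in shape)] = grid
        return full

    for idx, grid in coeffs.coeffs.items():
        term = upsample(grid)
        for axis, ax_order in enumerate(idx):
            term = ndimage.convolve1d(
                term,
                bank.synthesis_1d[:, ax_order],
                axis=axis,
                mode="constant",
                cval=0.0,
            )
        acc += term

    # accumulated squared-window weight of the lattice, separable per axis
    w = bank.window.sampled_squared()
    norm = upsample(np.ones(coeffs.grid_shape))
    for axis in range(len(shape)):
        norm = ndimage.convolve1d(norm, w, axis=axis, mode="constant", cval=0.0)
    # the sqrt(Z) per axis in the synthesis kernels cancels the 1/sqrt(Z)
    # of the analysis kernels; norm is strictly positive for stride <= M
    acc /= norm
    return Volume(acc)


def ac_energy_by_order(coeffs: HermiteCoefficients) -> np.ndarray:
    """Total squared coefficient energy per order n = 1..N (AC part)."""
    out = np.zeros(coeffs.order_max)
    for idx, grid in coeffs.coeffs.items():
        n = sum(idx)
        if n >= 1:
            out[n - 1] += float(np.sum(grid**2))
    return out
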