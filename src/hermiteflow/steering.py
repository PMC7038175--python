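"""Orientation estimation and steering of Hermite coefficients.

The first-order Hermite coefficients approximate the local gradient, whose
direction (theta in-plane, phi elevation from the z-axis) defines the axis
of maximum local energy.  Steering projects each order's Cartesian
coefficient vector onto a frame rotated so that its first axis points along
that direction.

Rotation of order-n coefficients is an orthonormal change of basis: in the
normalized monomial (Bargmann) basis ``x^a y^b z^c / sqrt(a! b! c!)`` a
spatial rotation acts per order as an orthogonal matrix, which we factor
into two planar rotations — Rz(theta) about z, then Ry(phi - pi/2) about y.
At (theta=0, phi=pi/2) the map is the identity, per-order energy is
conserved exactly, and steering to the local gradient direction sends the
whole first-order energy into the on-axis coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Optional, Tuple

import numpy as np

from .hermite import HermiteCoefficients

__all__ = [
    "OrientationField",
    "SteeredCoefficients",
    "angular_function",
    "estimate_orientation",
    "steer",
    "steered_profile",
]


@dataclass
class OrientationField:
    """Per-position orientation of maximum energy.

    ``theta``: in-plane angle (radians); ``phi``: elevation measured from
    the z-axis toward the xy-plane (absent for 2D); ``energy``: first-order
    gradient magnitude, used to flag low-confidence (flat) voxels where the
    angles fall back to the convention value 0.
    """

    theta: np.ndarray
    phi: Optional[np.ndarray]
    energy: np.ndarray

    @property
    def ndim(self) -> int:
        return 2 if self.phi is None else 3

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.theta.shape

    def direction(self) -> Tuple[np.ndarray, ...]:
        """Unit vector of the orientation axis per voxel."""
        if self.phi is None:
            return (np.cos(self.theta), np.sin(self.theta))
        sp = np.sin(self.phi)
        return (
            np.cos(self.theta) * sp,
            np.sin(self.theta) * sp,
            np.cos(self.phi),
        )


@dataclass
class SteeredCoefficients:
    """Hermite coefficients in the locally rotated (steered) frame.

    Index tuples keep their meaning per axis of the *rotated* frame; the
    on-axis index of order n is ``(n, 0)`` / ``(n, 0, 0)``.
    """

    coeffs: Dict[Tuple[int, ...], np.ndarray]
    orientation: OrientationField
    order_max: int

    def order(self, n: int) -> Dict[Tuple[int, ...], np.ndarray]:
        return {k: v for k, v in self.coeffs.items() if sum(k) == n}

    def on_axis(self, n: int) -> np.ndarray:
        ndim = self.orientation.ndim
        return self.coeffs[(n,) + (0,) * (ndim - 1)]

    def __getitem__(self, idx):
        return self.coeffs[idx]


def angular_function(j: int, k: int, angle) -> np.ndarray:
    """Cartesian angular function ``sqrt(C(k,j)) cos^j(angle) sin^{k-j}(angle)``.

    Expresses the directional selectivity of the order-k filters; for each
    k the squared functions sum to 1 over j (binomial identity).
    """
    if j < 0 or k < 0 or j > k:
        raise ValueError("need 0 <= j <= k")
    a = np.asarray(angle, dtype=np.float64)
    return math.sqrt(math.comb(k, j)) * np.cos(a) ** j * np.sin(a) ** (k - j)


def estimate_orientation(coeffs: HermiteCoefficients) -> OrientationField:
    """Orientation of maximum energy from the first-order coefficients.

    theta = atan2(L_010, L_100); phi = atan2(hypot(L_100, L_010), L_001)
    (quadrant-aware).  Voxels with zero gradient get theta = phi = 0 and
    are flagged through the energy grid.
    """
    ndim = coeffs.ndim
    try:
        if ndim == 2:
            gx = coeffs[(1, 0)]
            gy = coeffs[(0, 1)]
        else:
            gx = coeffs[(1, 0, 0)]
            gy = coeffs[(0, 1, 0)]
            gz = coeffs[(0, 0, 1)]
    except KeyError as exc:
        raise ValueError("first-order coefficients missing") from exc

    def principal(angle):
        # arctan2 hits -pi exactly on the negative real axis; fold it to
        # +pi so angles lie in the half-open interval (-pi, pi]
        return np.where(angle <= -np.pi, np.pi, angle)

    if ndim == 2:
        energy = np.hypot(gx, gy)
        theta = principal(np.arctan2(gy, gx))
        theta = np.where(energy == 0, 0.0, theta)
        return OrientationField(theta=theta, phi=None, energy=energy)

    rho = np.hypot(gx, gy)
    energy = np.sqrt(gx**2 + gy**2 + gz**2)
    theta = np.where(rho == 0, 0.0, principal(np.arctan2(gy, gx)))
    phi = principal(np.arctan2(rho, gz))
    phi = np.where(energy == 0, 0.0, phi)
    return OrientationField(theta=theta, phi=phi, energy=energy)


# ---------------------------------------------------------------------------
# planar rotation of coefficient stacks in the normalized monomial basis


@lru_cache(maxsize=None)
def _planar_tables(m: int):
    """Expansion tables for a planar rotation acting on degree-m pairs.

    Substitution x -> c*x + s*y, y -> -s*x + c*y on the normalized
    monomials ``x^a y^b / sqrt(a! b!)``.  Returns a dict mapping
    ``(u, (a, b))`` (output exponent of x, input pair) to a list of
    ``(weight, p, q)`` terms meaning ``weight * c^p * s^q``.
    """
    tables: Dict[Tuple[int, Tuple[int, int]], list] = {}
    for a in range(m + 1):
        b = m - a
        norm_in = math.sqrt(math.factorial(a) * math.factorial(b))
        accum: Dict[int, Dict[Tuple[int, int], float]] = {}
        # (c x + s y)^a: x-power i, y-power a-i;  (-s x + c y)^b: x-power
        # b-j, y-power j, sign (-1)^(b-j)
        for i in range(a + 1):
            for j in range(b + 1):
                u = i + (b - j)
                coef = (
                    math.comb(a, i)
                    * math.comb(b, j)
                    * (-1) ** (b - j)
                )
                p = i + j  # power of c
                q = (a - i) + (b - j)  # power of s
                accum.setdefault(u, {})
                accum[u][(p, q)] = accum[u].get((p, q), 0.0) + coef
        for u, terms in accum.items():
            norm_out = math.sqrt(math.factorial(u) * math.factorial(m - u))
            entry = [
                (w * norm_out / norm_in, p, q)
                for (p, q), w in terms.items()
                if w != 0.0
            ]
            tables[(u, (a, b))] = entry
    return tables


def _apply_planar(
    coeffs: Dict[Tuple[int, ...], np.ndarray],
    cos_grid: np.ndarray,
    sin_grid: np.ndarray,
    axis_a: int,
    axis_b: int,
    order_max: int,
) -> Dict[Tuple[int, ...], np.ndarray]:
    """Rotate coefficient stacks in the (axis_a, axis_b) index plane."""
    max_pow = order_max
    cpow = [np.ones_like(cos_grid)]
    spow = [np.ones_like(sin_grid)]
    for _ in range(max_pow):
        cpow.append(cpow[-1] * cos_grid)
        spow.append(spow[-1] * sin_grid)

    out: Dict[Tuple[int, ...], np.ndarray] = {}
    # group indices by their exponents outside the rotation plane
    groups: Dict[Tuple[Tuple[int, ...], int], Dict[Tuple[int, int], np.ndarray]] = {}
    for idx, grid in coeffs.items():
        rest = tuple(
            v for ax, v in enumerate(idx) if ax not in (axis_a, axis_b)
        )
        m = idx[axis_a] + idx[axis_b]
        groups.setdefault((rest, m), {})[(idx[axis_a], idx[axis_b])] = grid

    for (rest, m), block in groups.items():
        tables = _planar_tables(m)
        for u in range(m + 1):
            acc = None
            for (a, b), grid in block.items():
                for w, p, q in tables[(u, (a, b))]:
                    term = w * cpow[p] * spow[q] * grid
                    acc = term if acc is None else acc + term
            idx_out = [0] * (len(rest) + 2)
            rest_iter = iter(rest)
            for ax in range(len(idx_out)):
                if ax == axis_a:
                    idx_out[ax] = u
                elif ax == axis_b:
                    idx_out[ax] = m - u
                else:
                    idx_out[ax] = next(rest_iter)
            out[tuple(idx_out)] = acc
    return out


def steer(
    coeffs: HermiteCoefficients, orientation: OrientationField
) -> SteeredCoefficients:
    """Project Cartesian coefficients onto the locally oriented frame.

    Implemented as an order-preserving orthonormal map: a rotation by
    -theta in the (x, y) index plane followed by one aligning x with the
    elevation phi in the (x, z) plane.  Steering with (theta=0, phi=pi/2)
    is the identity on all orders.
    """
    shape = coeffs.grid_shape
    if orientation.shape != shape:
        raise ValueError(
            f"orientation grids {orientation.shape} do not match "
            f"coefficient grids {shape}"
        )
    n = coeffs.order_max
    stacks = {k: v for k, v in coeffs.coeffs.items()}
    # _apply_planar realizes the transpose of the substitution by (c, s);
    # passing -s therefore rotates the coefficient frame *toward* the
    # orientation: order-1 output x-component = c*Lx + s*Ly
    ct, st = np.cos(orientation.theta), np.sin(orientation.theta)
    if coeffs.ndim == 2:
        rotated = _apply_planar(stacks, ct, -st, 0, 1, n)
    else:
        if orientation.phi is None:
            raise ValueError("3D steering needs the elevation angle phi")
        step1 = _apply_planar(stacks, ct, -st, 0, 1, n)
        # then align the first axis with the elevation phi (identity at
        # phi = pi/2): x-component <- sin(phi)*x + cos(phi)*z
        cp = np.sin(orientation.phi)
        sp = np.cos(orientation.phi)
        rotated = _apply_planar(step1, cp, -sp, 0, 2, n)
    return SteeredCoefficients(coeffs=rotated, orientation=orientation, order_max=n)


def steered_profile(
    coeffs: HermiteCoefficients,
    orientation: OrientationField,
    order: int,
    stacks: Optional[Dict[Tuple[int, ...], np.ndarray]] = None,
) -> np.ndarray:
    """On-axis steered coefficient of a given order, in closed form.

    Equals the ``(n, 0, 0)`` entry of :func:`steer` but needs only the
    multinomial directional projection
    ``sum sqrt(n!/(a! b! c!)) dx^a dy^b dz^c L_{a,b,c}``
    with (dx, dy, dz) the orientation unit vector.  ``stacks`` may override
    the coefficient grids (used for derivative stacks that rotate the same
    way as the coefficients themselves).
    """
    if order < 1 or order > coeffs.order_max:
        raise ValueError("order must be in 1..order_max")
    d = orientation.direction()
    source = stacks if stacks is not None else coeffs.coeffs
    acc = None
    fact_n = math.factorial(order)
    for idx, grid in source.items():
        if sum(idx) != order:
            continue
        w = math.sqrt(
            fact_n / math.prod(math.factorial(k) for k in idx)
        )
        term = w * grid
        for comp, power in zip(d, idx):
            if power:
                term = term * comp**power
        acc = term if acc is None else acc + term
    if acc is None:
        raise ValueError(f"no coefficients of order {order} present")
    return acc
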