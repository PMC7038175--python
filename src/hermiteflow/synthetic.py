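"""Synthetic motion phantoms with analytic ground-truth flow.

Emulates the study conditions of volumetric (cardiac-CT-like) motion
estimation without any external data: smooth band-limited textures under
known translation or rotation, and an ellipsoidal-shell "ventricle" that
contracts and dilates over a cycle of phases.  Intensities live on a
12-bit-like scale (background 0, shell ~2000), so the packaged noise
preset sigma in {0, 5, 10, 15, 20, 30} represents mild acquisition noise,
as in CT practice.

Each frame after the first is produced by resampling the previous frame
with the same linear interpolator the flow estimator uses for warping, so
the sequence is exactly consistent with the returned ground-truth motion
(up to the interpolator for non-rigid fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .flow import FlowField, warp

__all__ = [
    "PhantomSpec",
    "NOISE_SIGMA_PRESET",
    "generate",
    "add_noise",
    "smooth_texture",
    "endpoint_error",
]

#: noise standard deviations of the robustness protocol (stored-scale units)
NOISE_SIGMA_PRESET: Tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0)

#: intensity of the ellipsoidal shell on the 12-bit-like stored scale
SHELL_INTENSITY = 2000.0
#: peak-to-peak amplitude of the additive texture
TEXTURE_CONTRAST = 600.0


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic sequence.

    ``kind``: one of translation / rotation / beating_ellipsoid;
    ``amplitude``: motion magnitude in voxels (per-transition shift for
    translation, peak contraction displacement at the shell for the
    ellipsoid); ``phases``: number of time steps (10 emulates the 0-90%
    cardiac cycle positions); ``correlation_length``: texture smoothness
    in voxels; ``noise_sigma``: additive zero-mean Gaussian noise on the
    stored intensity scale.  Same spec + seed always yields bit-identical
    output.
    """

    kind: str = "beating_ellipsoid"
    shape: Tuple[int, ...] = (48, 48, 48)
    amplitude: float = 2.0
    direction: Optional[Tuple[float, ...]] = None
    phases: int = 10
    correlation_length: float = 4.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if self.kind not in ("translation", "rotation", "beating_ellipsoid"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "beating_ellipsoid" and min(self.shape) < 16:
            raise ValueError("beating_ellipsoid needs >= 16 voxels per axis")
        if self.phases < 2:
            raise ValueError("need at least 2 phases")


def smooth_texture(
    shape: Tuple[int, ...],
    correlation_length: float,
    contrast: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian random field: white noise smoothed to the
    requested correlation length, rescaled to the requested contrast
    (std), zero mean."""
    noise = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(noise, sigma=correlation_length / 2.0, mode="wrap")
    std = fieldv.std()
    if std > 0:
        fieldv *= contrast / std
    return fieldv


def add_noise(volume, sigma: float, seed: Optional[int] = None) -> np.ndarray:
    """Additive zero-mean Gaussian noise of the given standard deviation
    on the stored intensity scale; sigma = 0 returns the input unchanged."""
    from .hermite import as_array

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    data = as_array(volume)
    if sigma == 0:
        return data.copy()
    rng = np.random.default_rng(seed)
    return data + rng.normal(0.0, sigma, size=data.shape)


def _face_taper(shape: Tuple[int, ...], margin: int = 4) -> np.ndarray:
    """Smooth weight falling to zero at the volume faces, so displacement
    fields remain self-consistent under edge-clamped warping."""
    w = np.ones(shape)
    for axis, s in enumerate(shape):
        x = np.arange(s, dtype=np.float64)
        ramp = np.minimum(x, s - 1 - x) / max(margin, 1)
        prof = np.clip(ramp, 0.0, 1.0)
        prof = 0.5 - 0.5 * np.cos(np.pi * prof)  # smoothstep
        view = [None] * len(shape)
        view[axis] = slice(None)
        w = w * prof[tuple(view)]
    return w


def radius_schedule(phases: int, dilation_ratio: float = 0.25) -> np.ndarray:
    """Normalized shell-radius offset per phase (units of the contraction
    amplitude): piecewise cosine, end-contraction (-1) at 30% of the cycle
    and end-dilation (+dilation_ratio) at 70%, returning to rest."""
    f = np.arange(phases) / phases
    out = np.zeros(phases)
    for k, fk in enumerate(f):
        if fk <= 0.3:
            out[k] = -0.5 * (1 - np.cos(np.pi * fk / 0.3))
        elif fk <= 0.7:
            out[k] = -1.0 + (1 + dilation_ratio) * 0.5 * (
                1 - np.cos(np.pi * (fk - 0.3) / 0.4)
            )
        else:
            out[k] = dilation_ratio * 0.5 * (1 + np.cos(np.pi * (fk - 0.7) / 0.3))
    return out


def _ellipsoid_frame(
    shape: Tuple[int, ...],
    radii: Tuple[float, ...],
    thickness: float,
    texture: np.ndarray,
) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(
        *[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"
    )
    rho = np.sqrt(
        sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    )
    rbar = float(np.mean(radii))
    shell = SHELL_INTENSITY * np.exp(-(((rho - 1.0) * rbar) / thickness) ** 2)
    return shell + texture * np.exp(-0.5 * ((rho - 1.0) * rbar / (2 * thickness)) ** 2)


def _radial_flow(
    shape: Tuple[int, ...],
    radii: Tuple[float, ...],
    scale_from: float,
    scale_to: float,
    taper: np.ndarray,
) -> FlowField:
    """Analytic displacement of a radially scaling shell: a point at x
    moves to center + (x - center) * (scale_to / scale_from), tapered to
    zero at the faces."""
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.meshgrid(
        *[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"
    )
    factor = scale_to / scale_from - 1.0
    comps = tuple((g - c) * factor * taper for g, c in zip(grids, center))
    return FlowField(comps)


def generate(spec: PhantomSpec) -> Tuple[List[np.ndarray], List[FlowField]]:
    """Generate (volumes, ground_truth_flows).

    ``flows[k]`` is the forward flow from phase k to k+1 in the package's
    convention: volume[k] at x matches volume[k+1] at x + w(x).
    """
    rng = np.random.default_rng(spec.seed)
    d = len(spec.shape)
    texture = smooth_texture(
        spec.shape, spec.correlation_length, TEXTURE_CONTRAST, rng
    )

    volumes: List[np.ndarray] = []
    flows: List[FlowField] = []

    if spec.kind == "translation":
        direction = spec.direction or (1.0,) + (0.0,) * (d - 1)
        norm = np.sqrt(sum(c**2 for c in direction))
        step = tuple(
            spec.amplitude * c / norm if norm > 0 else 0.0 for c in direction
        )
        base = texture - texture.min() + 100.0
        volumes.append(base)
        for k in range(1, spec.phases):
            gt = FlowField(tuple(np.full(spec.shape, s) for s in step))
            # rigid shifts of the periodic band-limited texture are applied
            # spectrally, which is exact; linear resampling would low-pass
            # half-voxel shifts and break constancy by construction
            shifted = ndimage.fourier_shift(
                np.fft.fftn(base), [k * s for s in step]
            )
            volumes.append(np.real(np.fft.ifftn(shifted)))
            flows.append(gt)
    elif spec.kind == "rotation":
        if d != 2 and d != 3:
            raise ValueError("rotation phantom supports 2D/3D")
        base = texture - texture.min() + 100.0
        center = [(s - 1) / 2.0 for s in spec.shape]
        ref_radius = min(spec.shape) / 4.0
        dtheta = spec.amplitude / ref_radius
        grids = np.meshgrid(
            *[np.arange(s, dtype=np.float64) for s in spec.shape], indexing="ij"
        )
        x0 = grids[0] - center[0]
        y0 = grids[1] - center[1]
        c, s = np.cos(dtheta), np.sin(dtheta)
        # in-plane rigid rotation about the center (axes 0-1); the forward
        # flow rotates by +dtheta, the generating backward warp by -dtheta
        # (its exact inverse), keeping sequence and ground truth consistent
        fwd = [(c * x0 - s * y0) - x0, (s * x0 + c * y0) - y0]
        bwd = [(c * x0 + s * y0) - x0, (-s * x0 + c * y0) - y0]
        zeros = [np.zeros(spec.shape)] * (d - 2)
        volumes.append(base)
        for _ in range(spec.phases - 1):
            gt = FlowField(tuple(comp.copy() for comp in fwd + zeros))
            back = FlowField(tuple(comp.copy() for comp in bwd + zeros))
            volumes.append(warp(volumes[-1], back))
            flows.append(gt)
    else:  # beating_ellipsoid
        radii = tuple(0.3 * s for s in spec.shape)
        rbar = float(np.mean(radii))
        thickness = max(2.0, 0.08 * rbar)
        taper = _face_taper(spec.shape)
        offsets = radius_schedule(spec.phases)
        scales = 1.0 + spec.amplitude * offsets / rbar
        volumes.append(_ellipsoid_frame(spec.shape, radii, thickness, texture))
        for k in range(spec.phases - 1):
            gt = _radial_flow(spec.shape, radii, scales[k], scales[k + 1], taper)
            neg = FlowField(tuple(-c for c in gt.components))
            volumes.append(warp(volumes[-1], neg))
            flows.append(gt)

    if spec.noise_sigma > 0:
        child = np.random.default_rng(spec.seed)
        noise_seeds = child.integers(0, 2**31 - 1, size=len(volumes))
        volumes = [
            add_noise(v, spec.noise_sigma, seed=int(s))
            for v, s in zip(volumes, noise_seeds)
        ]
    return volumes, flows


def endpoint_error(
    estimated: FlowField, truth: FlowField, margin: int = 4
) -> float:
    """Mean Euclidean distance between estimated and true displacement,
    over the interior (a margin equal to the analysis window is excluded,
    where the windowed transform needs boundary extrapolation)."""
    if estimated.shape != truth.shape:
        raise ValueError("flow fields must share a shape")
    core = tuple(slice(margin, s - margin) for s in estimated.shape)
    sq = sum(
        (e[core] - t[core]) ** 2
        for e, t in zip(estimated.components, truth.components)
    )
    return float(np.mean(np.sqrt(sq)))
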