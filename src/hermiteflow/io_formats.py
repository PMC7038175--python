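"""Readers and writers for volumes, masks, flow fields and coefficients.

Axis convention (documented once, used everywhere): in-memory arrays are
indexed ``(x, y, z) = (axis 0, 1, 2)``; on disk the x index varies
fastest.  NIfTI data already follow this layout; multi-page TIFF stacks
store pages as z slices of (y, x) planes and are transposed on the way
in/out; legacy-VTK point data are written x-fastest (Fortran raveling).
Masks are 8-bit with nonzero meaning inside.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .hermite import HermiteCoefficients, Volume, as_array, as_volume
from .flow import FlowField

__all__ = [
    "VolumeSeries",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_flo",
    "write_flo",
    "read_vtk_flow",
    "write_vtk_flow",
    "save_flow",
    "load_flow",
    "save_coefficients",
    "load_coefficients",
    "read_dicom_series",
    "write_metrics_table",
]

FLO_MAGIC = 202021.25
#: displacement values above this are "unknown flow" sentinels
FLO_UNKNOWN = 1e9


@dataclass
class VolumeSeries:
    """Time-ordered volumes sharing one shape and spacing.

    ``phase_labels`` name the cycle positions (e.g. "0%".."90%").
    """

    volumes: List[Volume]
    spacing: Tuple[float, ...]
    phase_labels: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError(f"volumes have inconsistent shapes {shapes}")
        if not self.phase_labels:
            self.phase_labels = [
                f"{100 * k // max(len(self.volumes), 1)}%"
                for k in range(len(self.volumes))
            ]
        if len(set(self.phase_labels)) != len(self.phase_labels):
            raise ValueError("phase labels must be unique")

    def __len__(self) -> int:
        return len(self.volumes)


# ---------------------------------------------------------------------------
# volumes


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if name.endswith((".npy", ".npz")):
        return "raw"
    raise IOError(
        f"cannot infer volume format from {path.name!r}; expected "
        ".nii/.nii.gz, .tif/.tiff or .npy/.npz"
    )


def read_volume(path, format: str = "auto") -> Volume:
    """Read a scalar grid as float64 with recorded spacing.

    Integer data (e.g. 12-bit CT in 16-bit containers) keep their stored
    range; no rescaling is applied.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        return Volume(data, spacing=spacing)
    if fmt == "tiff":
        import tifffile

        data = tifffile.imread(str(path)).astype(np.float64)
        # pages (z), rows (y), cols (x)  ->  (x, y[, z])
        data = data.T
        return Volume(data)
    if fmt == "raw":
        if path.suffix == ".npz":
            with np.load(path) as npz:
                data = npz["data"]
                spacing = tuple(npz["spacing"]) if "spacing" in npz else None
            return Volume(np.asarray(data, dtype=np.float64), spacing=spacing)
        return Volume(np.load(path).astype(np.float64))
    raise IOError(f"unknown volume format {fmt!r}")


def write_volume(volume, path, format: str = "auto") -> None:
    vol = as_volume(volume)
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0] * (4 - vol.ndim))
        img = nib.Nifti1Image(vol.data, affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(str(path), vol.data.T)
    elif fmt == "raw":
        np.savez(path, data=vol.data, spacing=np.asarray(vol.spacing))
    else:
        raise IOError(f"unknown volume format {fmt!r}")


def read_mask(path) -> np.ndarray:
    """Binary mask: nonzero voxels are inside."""
    return read_volume(path).data != 0


def read_dicom_series(directory) -> Volume:
    """Read a single-series DICOM directory as one volume (read-only
    adapter; slices ordered by InstanceNumber, spacing from pixel spacing
    and slice separation)."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise IOError("DICOM support requires the 'pydicom' package") from exc
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise IOError(f"no DICOM files found in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: int(getattr(s, "InstanceNumber", 0)))
    data = np.stack([s.pixel_array.astype(np.float64).T for s in slices], axis=-1)
    first = slices[0]
    px = getattr(first, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(first, "SliceThickness", 1.0))
    return Volume(data, spacing=(float(px[1]), float(px[0]), dz))


# ---------------------------------------------------------------------------
# Middlebury .flo (2D flow)


def read_flo(path) -> Tuple[FlowField, np.ndarray]:
    """Read a Middlebury .flo file.

    Returns ``(flow, valid)`` on the package's (x, y) axis order; voxels
    whose stored magnitude exceeds the unknown-flow sentinel are zeroed in
    the flow and flagged False in ``valid``.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = struct.unpack("<f", fh.read(4))[0]
        if abs(magic - FLO_MAGIC) > 1e-3:
            raise IOError(f"{path.name}: bad .flo magic number {magic!r}")
        width, height = struct.unpack("<ii", fh.read(8))
        data = np.frombuffer(fh.read(), dtype="<f4")
    if data.size != width * height * 2:
        raise IOError(f"{path.name}: truncated .flo payload")
    data = data.reshape(height, width, 2).astype(np.float64)
    u = data[:, :, 0].T  # (x, y)
    v = data[:, :, 1].T
    valid = (np.abs(u) < FLO_UNKNOWN) & (np.abs(v) < FLO_UNKNOWN)
    u = np.where(valid, u, 0.0)
    v = np.where(valid, v, 0.0)
    return FlowField((u, v)), valid


def write_flo(flow: FlowField, path) -> None:
    """Write a 2D flow in the Middlebury dialect (little-endian float32,
    magic 202021.25, interleaved u, v, row-major)."""
    if flow.ndim != 2:
        raise ValueError(".flo files hold 2D flow only")
    u, v = (c.T.astype("<f4") for c in flow.components)  # back to (y, x)
    h, w = u.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack("<f", FLO_MAGIC))
        fh.write(struct.pack("<ii", w, h))
        np.stack([u, v], axis=-1).tofile(fh)


# ---------------------------------------------------------------------------
# VTK legacy ASCII (3D flow for glyph rendering)


def write_vtk_flow(flow: FlowField, path, volume=None, spacing=None) -> None:
    """Write a 3D flow as a legacy-ASCII VTK structured-points file with a
    3-component ``flow`` vector array (plus an optional ``intensity``
    scalar array), renderable as glyphs in ParaView-class viewers."""
    if flow.ndim != 3:
        raise ValueError("VTK export is for 3D flow; use .flo for 2D")
    shape = flow.shape
    spacing = spacing or (1.0, 1.0, 1.0)
    n = int(np.prod(shape))
    comps = [c.ravel(order="F") for c in flow.components]  # x fastest
    lines = [
        "# vtk DataFile Version 3.0",
        "hermiteflow flow field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        "DIMENSIONS {} {} {}".format(*shape),
        "ORIGIN 0 0 0",
        "SPACING {} {} {}".format(*spacing),
        f"POINT_DATA {n}",
        "VECTORS flow float",
    ]
    vec = np.stack(comps, axis=1)
    lines.extend(" ".join(f"{x:.7g}" for x in row) for row in vec)
    if volume is not None:
        data = as_array(volume)
        if data.shape != shape:
            raise ValueError("intensity volume shape does not match flow")
        lines.append("SCALARS intensity float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{x:.7g}" for x in data.ravel(order="F"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_flow(path) -> Tuple[FlowField, Optional[np.ndarray]]:
    """Read back a legacy-ASCII structured-points flow file (the writer's
    counterpart, used for round-trip checks and probing)."""
    tokens = Path(path).read_text().split("\n")
    shape = None
    i = 0
    vectors = None
    scalars = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("DIMENSIONS"):
            shape = tuple(int(t) for t in line.split()[1:4])
        elif line.startswith("VECTORS"):
            n = int(np.prod(shape))
            flat = " ".join(tokens[i + 1 : i + 1 + n]).split()
            vectors = np.array(flat, dtype=np.float64).reshape(n, 3)
            i += n
        elif line.startswith("SCALARS"):
            n = int(np.prod(shape))
            flat = " ".join(tokens[i + 2 : i + 2 + n]).split()
            scalars = np.array(flat, dtype=np.float64)
            i += n + 1
        i += 1
    if shape is None or vectors is None:
        raise IOError(f"{path}: not a structured-points flow file")
    comps = tuple(
        vectors[:, k].reshape(shape, order="F") for k in range(3)
    )
    vol = scalars.reshape(shape, order="F") if scalars is not None else None
    return FlowField(comps), vol


# ---------------------------------------------------------------------------
# named-array containers (flow fields and coefficient sets)


def save_flow(flow: FlowField, path) -> None:
    arrays = {f"component_{k}": c for k, c in enumerate(flow.components)}
    np.savez(path, ndim=np.asarray(flow.ndim), **arrays)


def load_flow(path) -> FlowField:
    with np.load(path) as npz:
        d = int(npz["ndim"])
        comps = tuple(npz[f"component_{k}"] for k in range(d))
    return FlowField(comps)


def save_coefficients(coeffs: HermiteCoefficients, path) -> None:
    """Persist a coefficient set: one named array per index triple plus
    metadata (N, window size, sigma, stride, source shape)."""
    arrays = {
        "idx_" + "_".join(map(str, idx)): grid
        for idx, grid in coeffs.coeffs.items()
    }
    np.savez(
        path,
        order_max=np.asarray(coeffs.order_max),
        sigma=np.asarray(coeffs.sigma),
        stride=np.asarray(coeffs.stride),
        window_size=np.asarray(coeffs.window_size),
        source_shape=np.asarray(coeffs.source_shape),
        **arrays,
    )


def load_coefficients(path) -> HermiteCoefficients:
    with np.load(path) as npz:
        coeffs = {
            tuple(int(t) for t in key[4:].split("_")): npz[key]
            for key in npz.files
            if key.startswith("idx_")
        }
        return HermiteCoefficients(
            coeffs=coeffs,
            order_max=int(npz["order_max"]),
            sigma=float(npz["sigma"]),
            stride=int(npz["stride"]),
            window_size=int(npz["window_size"]),
            source_shape=tuple(int(s) for s in npz["source_shape"]),
        )


# ---------------------------------------------------------------------------
# summary tables


def write_metrics_table(reports, path, labels: Optional[Sequence[str]] = None) -> None:
    """Delimited text table of per-transition IE/NE."""
    rows = ["transition\tie\tne"]
    for k, rep in enumerate(reports):
        label = labels[k] if labels else str(k)
        rows.append(f"{label}\t{rep.ie:.6g}\t{rep.ne:.6g}")
    Path(path).write_text("\n".join(rows) + "\n")


def write_manifest(path, entries: Dict) -> None:
    Path(path).write_text(json.dumps(entries, indent=2) + "\n")
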