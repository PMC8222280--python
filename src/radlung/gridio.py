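"""Image-grid data model and NIfTI I/O.

Every volume the pipeline touches — CT in Hounsfield units, dose grids in
Gy, Jacobian maps, binary masks, displacement fields — lives on an
axis-aligned 3D lattice described by a shape, a positive per-axis spacing
(mm/voxel) and a world origin (mm).  World position of voxel ``(i, j, k)``
is ``origin + index * spacing``.  The pipeline never resamples: masks and
fields must share their reference grid's geometry exactly, and voxel-wise
comparisons presuppose pre-registered, common-grid data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "ImageGrid",
    "BinaryMask",
    "VectorField",
    "DynamicSeries",
    "FormatError",
    "GeometryMismatchError",
    "load_volume",
    "save_volume",
    "load_vector_field",
    "save_vector_field",
    "load_dynamic_series",
    "save_dynamic_series",
    "mask_volume_cc",
    "assert_same_geometry",
]

#: geometry comparison tolerance in mm
GEOMETRY_ATOL_MM = 1e-4


class FormatError(ValueError):
    """A file on disk does not have the expected layout."""


class GeometryMismatchError(ValueError):
    """Two grids that must share a lattice do not."""


def _as_vec3(x: Sequence[float], name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass
class ImageGrid:
    """A 3D scalar lattice (HU, Gy, or unitless) with spacing and origin."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(
                f"ImageGrid requires a 3D array, got {self.values.ndim}D"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageGrid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self, values: np.ndarray | None = None) -> "ImageGrid":
        """New grid on the same lattice, optionally with replacement values."""
        v = self.values.copy() if values is None else np.asarray(values)
        return ImageGrid(v, self.spacing.copy(), self.origin.copy())


@dataclass
class BinaryMask:
    """A boolean lattice sharing the geometry of a reference ImageGrid."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise FormatError(
                f"BinaryMask requires a 3D array, got {self.values.ndim}D"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    @classmethod
    def like(cls, ref: "ImageGrid | BinaryMask", values: np.ndarray) -> "BinaryMask":
        return cls(values, np.asarray(ref.spacing).copy(), np.asarray(ref.origin).copy())


@dataclass
class VectorField:
    """Per-voxel 3-vector displacement (mm), stored as ``u[..., 3]``."""

    u: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise FormatError(
                f"VectorField requires an (nx, ny, nz, 3) array, got {self.u.shape}"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("VectorField displacements must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]  # type: ignore[return-value]


@dataclass
class DynamicSeries:
    """Time-ordered, co-registered contrast-CT frames.

    ``times`` are acquisition times in seconds (strictly increasing);
    ``n_precontrast`` counts the frames acquired before contrast injection.
    """

    frames: list[ImageGrid]
    times: np.ndarray
    n_precontrast: int = 4

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("DynamicSeries needs at least 2 frames")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (len(self.frames),):
            raise ValueError("times must have one entry per frame")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("acquisition times must be strictly increasing")
        if not 0 < self.n_precontrast < len(self.frames):
            raise ValueError(
                f"n_precontrast must lie in (0, n_frames); got "
                f"{self.n_precontrast} of {len(self.frames)}"
            )
        ref = self.frames[0]
        for f in self.frames[1:]:
            assert_same_geometry(ref, f)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def geometry(self) -> ImageGrid:
        return self.frames[0]

    def stack(self) -> np.ndarray:
        """(n_frames, nx, ny, nz) view-free stack of frame values."""
        return np.stack([f.values for f in self.frames], axis=0)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _geometry_of(obj) -> tuple[tuple[int, ...], np.ndarray, np.ndarray]:
    if isinstance(obj, VectorField):
        return obj.shape, obj.spacing, obj.origin
    return obj.shape, np.asarray(obj.spacing), np.asarray(obj.origin)


def assert_same_geometry(a, b) -> None:
    """Raise :class:`GeometryMismatchError` unless ``a`` and ``b`` share a lattice.

    Shapes must match exactly; spacing and origin within 1e-4 mm.
    """
    sa, spa, oa = _geometry_of(a)
    sb, spb, ob = _geometry_of(b)
    if sa != sb:
        raise GeometryMismatchError(f"shape mismatch: {sa} vs {sb}")
    if not np.allclose(spa, spb, atol=GEOMETRY_ATOL_MM, rtol=0):
        raise GeometryMismatchError(f"spacing mismatch: {spa} vs {spb}")
    if not np.allclose(oa, ob, atol=GEOMETRY_ATOL_MM, rtol=0):
        raise GeometryMismatchError(f"origin mismatch: {oa} vs {ob}")


def mask_volume_cc(mask: BinaryMask) -> float:
    """Volume of the true voxels in cubic centimetres (exact)."""
    return mask.volume_cc


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _geometry_from_img(img) -> tuple[np.ndarray, np.ndarray]:
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3]).astype(float)
    origin = aff[:3, 3].astype(float)
    return spacing, origin


def load_volume(path: str | Path) -> ImageGrid:
    """Read a 3D scalar NIfTI volume.

    Raises :class:`FormatError` for 4D or otherwise non-scalar payloads
    (displacement fields go through :func:`load_vector_field`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(
            f"{path.name}: expected a 3D scalar volume, got {data.ndim}D "
            f"payload of shape {data.shape}"
        )
    spacing, origin = _geometry_from_img(img)
    return ImageGrid(np.asarray(data), spacing, origin)


def save_volume(grid: ImageGrid | BinaryMask, path: str | Path) -> None:
    """Write a grid (or mask, as uint8 0/1) to NIfTI."""
    if isinstance(grid, BinaryMask):
        data = grid.values.astype(np.uint8)
    else:
        if not np.all(np.isfinite(grid.values)):
            raise ValueError("refusing to save non-finite values")
        data = grid.values
    img = nib.Nifti1Image(data, _affine(np.asarray(grid.spacing), np.asarray(grid.origin)))
    nib.save(img, str(path))


def load_mask(path: str | Path, reference: ImageGrid | None = None) -> BinaryMask:
    g = load_volume(path)
    mask = BinaryMask(g.values > 0.5, g.spacing, g.origin)
    if reference is not None:
        assert_same_geometry(reference, mask)
    return mask


def load_vector_field(path: str | Path) -> VectorField:
    """Read a 3-component NIfTI vector image (shape (nx, ny, nz, 3), mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(
            f"{path.name}: expected a 3-component vector image, got shape {data.shape}"
        )
    spacing, origin = _geometry_from_img(img)
    return VectorField(data, spacing, origin)


def save_vector_field(field: VectorField, path: str | Path) -> None:
    img = nib.Nifti1Image(field.u, _affine(field.spacing, field.origin))
    nib.save(img, str(path))


def save_dynamic_series(series: DynamicSeries, directory: str | Path, stem: str = "frame") -> Path:
    """Write one NIfTI per frame plus a JSON sidecar; returns the sidecar path.

    Sidecar layout: ``{"frames": [...], "times_s": [...], "n_precontrast": int}``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(series.frames):
        name = f"{stem}_{i:03d}.nii.gz"
        save_volume(frame, directory / name)
        names.append(name)
    sidecar = directory / f"{stem}_series.json"
    sidecar.write_text(json.dumps({
        "frames": names,
        "times_s": [float(t) for t in series.times],
        "n_precontrast": int(series.n_precontrast),
    }, indent=1))
    return sidecar


def load_dynamic_series(sidecar: str | Path) -> DynamicSeries:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    frames = [load_volume(sidecar.parent / name) for name in meta["frames"]]
    return DynamicSeries(frames, np.asarray(meta["times_s"], dtype=float),
                         int(meta["n_precontrast"]))
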