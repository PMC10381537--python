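"""Anisotropic 3D intensity volumes and their file formats.

The carrier type :class:`Volume3D` holds a scalar intensity grid together
with its physical voxel spacing and origin.  The coordinate convention is
right-handed with the z axis vertical: the soil surface sits at z = 0 and
depths are negative.  Voxel index ``(i, j, k)`` maps to the physical center

    (x0 + i*dx,  y0 + j*dy,  z0 - k*dz)

so the slice index ``k`` grows downward, matching how axial MRI slices of a
soil column are stacked.

Supported formats: NIfTI-1 (``.nii`` / ``.nii.gz``, via nibabel) and a raw
binary array with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, FormatError, ValidationError

__all__ = ["Volume3D", "read_volume", "write_volume", "upsample_volume"]


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with physical metadata.

    Parameters
    ----------
    data
        Non-negative intensities, exactly three axes.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm, all positive.
    origin
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    z_down
        Axis convention flag: when True (default) the third index grows
        downward (physical z decreases with k).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    z_down: bool = field(default=True)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume data must have 3 axes, got {self.data.ndim}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacings must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValidationError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def voxel_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to physical mm coordinates (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        sz = -dz if self.z_down else dz
        return np.stack(
            [x0 + idx[..., 0] * dx, y0 + idx[..., 1] * dy, z0 + idx[..., 2] * sz],
            axis=-1,
        )

    def physical_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_physical` (continuous indices)."""
        pos = np.asarray(pos, dtype=float)
        dx, dy, dz = self.spacing
        x0, y0, z0 = self.origin
        sz = -dz if self.z_down else dz
        return np.stack(
            [
                (pos[..., 0] - x0) / dx,
                (pos[..., 1] - y0) / dy,
                (pos[..., 2] - z0) / sz,
            ],
            axis=-1,
        )

    def like(self, data: np.ndarray) -> "Volume3D":
        """New volume with the same grid metadata but different data."""
        return Volume3D(data, self.spacing, self.origin, self.z_down)

    def copy(self) -> "Volume3D":
        return self.like(self.data.copy())


def _affine(vol: Volume3D) -> np.ndarray:
    dx, dy, dz = vol.spacing
    sz = -dz if vol.z_down else dz
    aff = np.diag([dx, dy, sz, 1.0])
    aff[:3, 3] = vol.origin
    return aff


def read_volume(path: str | Path) -> Volume3D:
    """Read a volume from NIfTI-1 or raw + JSON sidecar.

    Spacing and origin are taken from the header/sidecar; intensities are
    returned unmodified.
    """
    path = Path(path)
    if path.suffix == ".raw":
        return _read_raw(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        return _read_nifti(path)
    if path.suffix == ".json":
        return _read_raw(path.with_suffix(".raw"))
    raise FormatError(f"unrecognized volume format: {path}")


def _read_nifti(path: Path) -> Volume3D:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for bad headers
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D data, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    aff = img.affine
    origin = tuple(float(v) for v in aff[:3, 3])
    z_down = bool(aff[2, 2] < 0)
    return Volume3D(data, tuple(float(z) for z in zooms), origin, z_down)


def _read_raw(path: Path) -> Volume3D:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar for raw volume: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"])
        dtype = np.dtype(meta["dtype"])
        spacing = tuple(meta["spacing_mm"])
        origin = tuple(meta.get("origin_mm", (0.0, 0.0, 0.0)))
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"corrupt sidecar {sidecar}: {exc}") from exc
    if len(shape) != 3:
        raise DimensionalityError(f"{path}: sidecar shape is not 3D: {shape}")
    data = np.fromfile(path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise FormatError(
            f"{path}: file size {data.size} does not match shape {shape}"
        )
    return Volume3D(data.reshape(shape), spacing, origin)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume; format chosen by extension (.nii/.nii.gz or .raw)."""
    vol.validate()
    path = Path(path)
    if path.suffix == ".raw":
        meta = {
            "shape": list(vol.shape),
            "dtype": vol.data.dtype.name,
            "spacing_mm": list(vol.spacing),
            "origin_mm": list(vol.origin),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))
        np.ascontiguousarray(vol.data).tofile(path)
        return
    img = nib.Nifti1Image(np.asarray(vol.data), _affine(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def upsample_volume(vol: Volume3D, factor: int = 2, order: int = 0) -> Volume3D:
    """Resample a volume onto a grid refined by ``factor`` along every axis.

    Doubling the per-axis resolution multiplies the voxel count by
    ``factor**3`` (8 for factor 2), the relation a super-resolution
    segmentation step relies on.  Interpolation order 0 replicates
    (segmentation masks); order 1 is trilinear.
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError(f"upsampling factor must be a positive integer: {factor}")
    factor = int(factor)
    data = ndimage.zoom(vol.data, factor, order=order, grid_mode=True, mode="nearest")
    spacing = tuple(s / factor for s in vol.spacing)
    # keep voxel-center alignment: new voxel 0 center shifts by (f-1)/(2f) spacing
    shift = [(factor - 1) / (2 * factor) * s for s in vol.spacing]
    x0, y0, z0 = vol.origin
    origin = (x0 - shift[0], y0 - shift[1], z0 + shift[2] if vol.z_down else z0 - shift[2])
    out = Volume3D(data, spacing, origin, vol.z_down)
    if data.size != vol.data.size * factor**3:
        warnings.warn("unexpected voxel count after upsampling")
    return out
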