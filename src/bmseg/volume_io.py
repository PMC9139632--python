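"""Volume containers and I/O.

All in-memory volumes use the axis order ``(slice z, row y, col x)`` with
0-based indices; spacing and origin follow the same order in millimetres.
NIfTI files are reoriented to the closest canonical (RAS) orientation on
read; the original affine is kept on the volume so a mask can be written
back onto the grid it came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised when a file or DICOM series cannot be interpreted as a volume."""


@dataclass
class ImageVolume:
    """A scalar 3D grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (slices, rows, cols)
        Voxel intensities in arbitrary units.
    spacing : tuple of float
        Voxel size ``(dz, dy, dx)`` in mm; all components positive.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm, ``(z, y, x)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_cc(self) -> float:
        return voxel_volume_cc(self.spacing)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel values."""
        return replace(self, data=np.asarray(data))


@dataclass
class LabelVolume(ImageVolume):
    """A binary mask aligned to an :class:`ImageVolume` grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"label values must be 0/1, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)


def voxel_volume_cc(spacing: tuple[float, float, float]) -> float:
    """Physical volume of one voxel in cc (1 cc = 1000 mm^3)."""
    dz, dy, dx = spacing
    if min(dz, dy, dx) <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return dz * dy * dx / 1000.0


def _affine_from_geometry(spacing, origin) -> np.ndarray:
    # data axes (z, y, x) -> world (x, y, z), RAS-like diagonal affine
    dz, dy, dx = spacing
    oz, oy, ox = origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def read_volume(path, format: str = "nifti", *, label: bool = False) -> ImageVolume:
    """Read a volume from disk.

    Parameters
    ----------
    path : path-like
        A ``.nii``/``.nii.gz`` file or a directory holding one DICOM series.
    format : {"nifti", "dicom_series"}
    label : bool
        Return a :class:`LabelVolume` (values coerced to {0,1} by ``> 0``).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if format == "nifti":
        vol = _read_nifti(path)
    elif format == "dicom_series":
        vol = _read_dicom_series(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if label:
        return LabelVolume(
            (vol.data > 0).astype(np.uint8), vol.spacing, vol.origin, vol.affine
        )
    return vol


def _read_nifti(path: Path) -> ImageVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D image, got shape {arr.shape}")
    # canonical nibabel order is (x, y, z); ours is (z, y, x)
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    tx, ty, tz = img.affine[:3, 3]
    return ImageVolume(data, spacing, (float(tz), float(ty), float(tx)), img.affine)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI. Labels are stored as unsigned 8-bit."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.uint8)
    arr = np.transpose(data, (2, 1, 0))  # back to (x, y, z)
    affine = vol.affine if vol.affine is not None else _affine_from_geometry(
        vol.spacing, vol.origin
    )
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))


def _read_dicom_series(path: Path) -> ImageVolume:
    if not path.is_dir():
        raise IOError(f"DICOM series path must be a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ""))
    datasets = []
    for f in files:
        if f.is_dir():
            continue
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise IOError(f"no readable DICOM slices under {path}")

    orientations = {tuple(np.round(ds.ImageOrientationPatient, 5)) for ds in datasets}
    if len(orientations) > 1:
        raise VolumeFormatError(
            f"{path}: slices have inconsistent ImageOrientationPatient tags"
        )
    spacings = {tuple(np.round(ds.PixelSpacing, 6)) for ds in datasets}
    if len(spacings) > 1:
        raise VolumeFormatError(f"{path}: slices have inconsistent PixelSpacing")

    iop = np.array(datasets[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(iop[:3], iop[3:])
    positions = [float(np.dot(normal, ds.ImagePositionPatient)) for ds in datasets]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    if len(datasets) > 1:
        steps = np.diff(positions)
        if steps.size and (steps.max() - steps.min()) > 1e-3:
            raise VolumeFormatError(f"{path}: non-uniform slice spacing")
        dz = float(abs(steps[0]))
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    data = np.stack([ds.pixel_array.astype(np.float32) for ds in datasets])
    dy, dx = (float(v) for v in datasets[0].PixelSpacing)
    ipp = datasets[0].ImagePositionPatient
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    return ImageVolume(data, (dz, dy, dx), origin)


def resample_volume(
    vol: ImageVolume,
    target_spacing: tuple[float, float, float],
    interpolation: str = "linear",
) -> ImageVolume:
    """Resample onto a grid with the requested spacing.

    The output extent along each axis is ``round(shape * spacing /
    target_spacing)`` with round-half-up, so e.g. 3 mm slices resampled to
    1 mm triple the slice count. Voxel ``j`` of the output samples the input
    at fractional index ``j * target / source`` (shared corner at index 0);
    values outside the grid take the nearest edge value.

    ``interpolation`` is ``"linear"`` for images, ``"nearest"`` for labels.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    src = vol.spacing
    new_shape = tuple(
        max(1, int(np.floor(n * s / t + 0.5)))
        for n, s, t in zip(vol.shape, src, target_spacing)
    )
    if new_shape == vol.shape and target_spacing == src:
        out = vol.data.copy()
    else:
        coords = np.meshgrid(
            *[
                np.arange(m) * (t / s)
                for m, s, t in zip(new_shape, src, target_spacing)
            ],
            indexing="ij",
        )
        order = 1 if interpolation == "linear" else 0
        out = ndimage.map_coordinates(
            vol.data.astype(np.float64, copy=False),
            np.stack([c.ravel() for c in coords]),
            order=order,
            mode="nearest",
        ).reshape(new_shape)
        if interpolation == "nearest":
            out = out.astype(vol.data.dtype)

    if isinstance(vol, LabelVolume):
        return LabelVolume(out.astype(np.uint8), target_spacing, vol.origin)
    return ImageVolume(out, target_spacing, vol.origin)
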