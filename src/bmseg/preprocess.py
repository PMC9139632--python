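"""Intensity normalization applied before patch extraction.

MR intensities carry no absolute scale, so the pipeline normalizes each
volume with three steps: multiplicative bias-field correction, percentile
intensity scaling to [0, 1], and gamma correction. The percentile window
defaults to (0.5, 99.5): clipping at the 0.5th and 99.5th percentiles of the
nonzero voxels removes contrast-agent and noise outliers without discarding
the dynamic range. Random gamma is a training-time augmentation; at
inference gamma is 1 (identity).
"""

from __future__ import annotations

import warnings

import numpy as np

from .volume_io import ImageVolume


class DegenerateInputError(ValueError):
    """Raised when a volume has no usable intensity content."""


def correct_bias_field(
    vol: ImageVolume,
    mode: str = "n4",
    *,
    degree: int = 2,
    shrink: int = 4,
    return_field: bool = False,
):
    """Remove a smooth multiplicative intensity inhomogeneity.

    ``mode="n4"`` delegates to SimpleITK's N4 implementation. ``mode=
    "polynomial"`` fits a polynomial of the given degree to the
    log-intensities of the nonzero voxels by least squares and divides the
    volume by the exponential of the fit (normalized to unit geometric
    mean), which recovers low-order synthetic fields exactly and requires
    no external machinery.

    Returns the corrected volume, or ``(corrected, field)`` when
    ``return_field`` is set.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if np.all(data == 0):
        raise DegenerateInputError("cannot bias-correct an all-zero volume")
    if data.min() < 0:
        data = data - data.min()
    mask = _tissue_mask(data)

    if mode == "n4":
        corrected, field = _n4_correct(data, mask, vol.spacing, shrink)
    elif mode == "polynomial":
        corrected, field = _polynomial_correct(data, mask, degree)
    else:
        raise ValueError(f"unknown bias mode {mode!r}")

    out = vol.with_data(corrected)
    if return_field:
        return out, field
    return out


def _tissue_mask(data: np.ndarray) -> np.ndarray:
    """Bright-voxel mask for the field fit; keeps air noise out of it."""
    nonzero = data[data > 0]
    if nonzero.size == 0:
        return data > 0
    thresh = 0.1 * np.percentile(nonzero, 99.5)
    mask = data > thresh
    # degenerate images (e.g. near-constant) fall back to all nonzero voxels
    return mask if mask.sum() >= 32 else data > 0


def _n4_correct(data: np.ndarray, tissue: np.ndarray, spacing, shrink: int):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(data.astype(np.float32))
    img.SetSpacing((spacing[2], spacing[1], spacing[0]))
    mask = sitk.GetImageFromArray(tissue.astype(np.uint8))
    mask.CopyInformation(img)
    small = sitk.Shrink(img, [shrink] * 3)
    small_mask = sitk.Shrink(mask, [shrink] * 3)
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.Execute(small, small_mask)
    log_field = corrector.GetLogBiasFieldAsImage(img)
    field = np.exp(sitk.GetArrayFromImage(log_field)).astype(np.float64)
    field = np.clip(field, 1e-6, None)
    return data / field, field


def _polynomial_correct(data: np.ndarray, mask: np.ndarray, degree: int):
    if mask.sum() < 32:
        raise DegenerateInputError("too few nonzero voxels to fit a bias field")
    # coordinates scaled to [-1, 1] keep the design matrix well conditioned
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in data.shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                cols.append((zz**i) * (yy**j) * (xx**k))
    design = np.stack([c[mask] for c in cols], axis=1)
    logv = np.log(data[mask])
    coef, *_ = np.linalg.lstsq(design, logv, rcond=None)
    log_field_full = np.tensordot(
        coef, np.stack(cols), axes=(0, 0)
    )
    # unit geometric mean over the mask: correction rescales nothing globally
    log_field_full -= log_field_full[mask].mean()
    field = np.exp(log_field_full)
    return data / field, field


def scale_intensity(
    vol: ImageVolume, lower_pct: float = 0.5, upper_pct: float = 99.5
) -> ImageVolume:
    """Clip at percentiles of the nonzero voxels and map affinely to [0, 1].

    Background air (zero voxels) is excluded from the percentile estimate so
    it cannot compress the tissue histogram; zeros map to 0 in the output.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError(f"need 0 <= lower < upper <= 100, got ({lower_pct}, {upper_pct})")
    data = np.asarray(vol.data, dtype=np.float64)
    nonzero = data[data != 0]
    if nonzero.size == 0:
        warnings.warn("constant (all-zero) volume: returning zeros", stacklevel=2)
        return vol.with_data(np.zeros_like(data))
    lo, hi = np.percentile(nonzero, [lower_pct, upper_pct])
    if hi <= lo:
        warnings.warn("degenerate intensity range: returning zeros", stacklevel=2)
        return vol.with_data(np.zeros_like(data))
    out = np.clip(data, lo, hi)
    out = (out - lo) / (hi - lo)
    out[data == 0] = 0.0
    return vol.with_data(out)


def apply_gamma(vol: ImageVolume, gamma: float) -> ImageVolume:
    """Voxelwise power-law mapping ``v ** gamma`` on intensities in [0, 1]."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    data = np.asarray(vol.data, dtype=np.float64)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("apply_gamma expects intensities in [0, 1]; scale first")
    return vol.with_data(data**gamma)


def preprocess_volume(
    vol: ImageVolume,
    *,
    bias_mode: str = "polynomial",
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
    gamma: float = 1.0,
) -> ImageVolume:
    """Full normalization chain: bias correction -> scaling -> gamma."""
    v = correct_bias_field(vol, mode=bias_mode)
    v = scale_intensity(v, lower_pct, upper_pct)
    return apply_gamma(v, gamma)
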