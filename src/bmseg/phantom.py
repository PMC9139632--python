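"""Synthetic contrast-enhanced head phantoms.

The generator emulates the statistical structure the pipeline assumes in
real T1Gd volumes: a bright brain ellipsoid with a skull rim on a dark
background, hyperintense ellipsoidal metastases whose volume distribution
is skewed toward sub-0.1 cc lesions, bright curvilinear vessel-like
distractors that act as false-positive bait, a smooth multiplicative bias
field, and additive Gaussian noise. It does not model MR physics (no pulse
sequences, no partial-volume blur beyond the soft lesion edge), so passing
phantom tests demonstrates the pipeline's mechanics, not clinical accuracy.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .inference import LesionSet, find_lesions
from .volume_io import ImageVolume, LabelVolume

TISSUE_INTENSITY = 100.0  # arbitrary units for normal brain parenchyma
SKULL_INTENSITY = 140.0


class GenerationError(RuntimeError):
    """Raised when the requested lesions cannot be placed without overlap."""


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic head volume.

    The default grid is a desk-scale 40 x 256 x 256 volume at
    (1, 0.78, 0.78) mm — the same field-of-view logic as a 1024-pixel
    0.195 mm clinical slice with 16x fewer in-plane voxels. Lesion volumes
    span 0.004–1.2 cc with 58.2% of draws below 0.1 cc, matching the
    small-lesion-dominated population the pipeline targets.
    """

    shape: tuple[int, int, int] = (40, 256, 256)
    spacing: tuple[float, float, float] = (1.0, 0.78, 0.78)
    n_lesions: int | tuple[int, int] = (3, 8)
    lesion_volume_range_cc: tuple[float, float] = (0.004, 1.2)
    small_fraction: float = 0.582
    lesion_contrast: float = 1.8
    n_vessels: int = 4
    bias_amplitude: float = 0.2
    noise_sigma: float = 0.03
    seed: int = 0


@dataclass
class LesionSpec:
    """Analytic description of one generated ellipsoidal lesion."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    target_volume_cc: float


def sample_lesion_volumes(
    n: int,
    range_cc: tuple[float, float] = (0.004, 1.2),
    small_fraction: float = 0.582,
    seed: int = 0,
) -> np.ndarray:
    """Draw lesion volumes from a two-component log-uniform mixture.

    With probability ``small_fraction`` a volume is drawn log-uniformly
    below 0.1 cc (within range), otherwise log-uniformly above, so the
    expected fraction of sub-0.1 cc lesions equals ``small_fraction``.
    """
    lo, hi = range_cc
    if not (0 < lo < hi):
        raise ValueError(f"invalid volume range {range_cc}")
    if not (0 <= small_fraction <= 1):
        raise ValueError(f"small_fraction must be in [0, 1], got {small_fraction}")
    rng = np.random.default_rng(seed)
    split = 0.1
    if hi <= split or lo >= split:
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    small = rng.random(n) < small_fraction
    out = np.empty(n)
    out[small] = np.exp(rng.uniform(np.log(lo), np.log(split), size=small.sum()))
    out[~small] = np.exp(rng.uniform(np.log(split), np.log(hi), size=(~small).sum()))
    return out


def add_bias_field(
    vol: ImageVolume, amplitude: float, seed: int = 0
) -> tuple[ImageVolume, np.ndarray]:
    """Multiply by a smooth low-frequency field in [1-amplitude, 1+amplitude].

    The field is a random superposition of the lowest cosine modes,
    normalized so its extrema hit the declared bounds exactly; it is
    returned alongside the biased volume for recovery tests.
    """
    if not (0 <= amplitude < 1):
        raise ValueError(f"amplitude must be in [0, 1), got {amplitude}")
    if amplitude == 0:
        return vol.with_data(vol.data.copy()), np.ones(vol.shape)
    rng = np.random.default_rng(seed)
    axes = [np.linspace(0, 1, n) for n in vol.shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    raw = np.zeros(vol.shape)
    for _ in range(4):
        freq = rng.uniform(0.25, 0.75, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        raw += rng.uniform(0.5, 1.0) * (
            np.cos(2 * np.pi * freq[0] * zz + phase[0])
            * np.cos(2 * np.pi * freq[1] * yy + phase[1])
            * np.cos(2 * np.pi * freq[2] * xx + phase[2])
        )
    raw -= (raw.max() + raw.min()) / 2
    raw /= np.abs(raw).max()
    bias = 1.0 + amplitude * raw
    return vol.with_data(vol.data * bias), bias


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    """Voxel centers inside the ellipsoid; evaluated on the bounding box."""
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(center_mm) / spacing
    half = np.asarray(semi_axes_mm) / spacing
    lo = np.maximum(np.floor(center - half - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + half + 2).astype(int), shape)
    out = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    grids = np.meshgrid(
        *[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"
    )
    q = sum(((g - c) / max(h, 1e-9)) ** 2 for g, c, h in zip(grids, center, half))
    out[tuple(slice(a, b) for a, b in zip(lo, hi))] = q <= 1.0
    return out


def _lesion_semi_axes(volume_cc: float, rng: np.random.Generator) -> np.ndarray:
    """Random mild anisotropy with (4/3)pi*a*b*c = volume (mm^3)."""
    ratios = rng.uniform(0.7, 1.3, size=3)
    ratios /= ratios.prod() ** (1 / 3)
    r = (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return r * ratios


def _draw_vessels(shape, spacing, brain, n_vessels, rng, keepout):
    """Bright curvilinear tubes inside the brain, away from lesions."""
    spacing = np.asarray(spacing, dtype=float)
    extent_mm = np.asarray(shape) * spacing
    centerline = np.zeros(shape, dtype=bool)
    radii_mm = []
    for _ in range(n_vessels):
        pos = extent_mm * rng.uniform(0.3, 0.7, size=3)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        n_steps = int(rng.integers(30, 80))
        step_mm = 1.0
        for _ in range(n_steps):
            idx = np.round(pos / spacing).astype(int)
            if np.all(idx >= 0) and np.all(idx < shape) and brain[tuple(idx)]:
                centerline[tuple(idx)] = True
            direction += 0.25 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = pos + step_mm * direction
        radii_mm.append(rng.uniform(0.4, 0.9))
    if not centerline.any():
        return np.zeros(shape, dtype=bool)
    dist = ndimage.distance_transform_edt(~centerline, sampling=spacing)
    vessels = (dist <= max(radii_mm)) & brain & ~keepout
    return vessels


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume, LesionSet]:
    """Build one phantom: image, exact ground-truth mask, and its lesion set."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = tuple(float(s) for s in spec.spacing)
    sp = np.asarray(spacing)
    extent_mm = np.asarray(shape) * sp

    # head: brain ellipsoid + skull rim
    center_mm = extent_mm / 2
    brain_axes = 0.40 * extent_mm
    skull_axes = 0.46 * extent_mm
    brain = _ellipsoid_mask(shape, spacing, center_mm, brain_axes)
    skull = _ellipsoid_mask(shape, spacing, center_mm, skull_axes) & ~brain

    image = np.zeros(shape, dtype=np.float64)
    image[brain] = TISSUE_INTENSITY
    image[skull] = SKULL_INTENSITY

    # lesions
    if isinstance(spec.n_lesions, tuple):
        n_lesions = int(rng.integers(spec.n_lesions[0], spec.n_lesions[1] + 1))
    else:
        n_lesions = int(spec.n_lesions)
    vol_seed = int(rng.integers(0, 2**31 - 1))
    volumes = sample_lesion_volumes(
        n_lesions, spec.lesion_volume_range_cc, spec.small_fraction, vol_seed
    )
    gt = np.zeros(shape, dtype=np.uint8)
    lesion_specs: list[LesionSpec] = []
    for vol_cc in volumes:
        placed = False
        semi = _lesion_semi_axes(vol_cc, rng)
        for _ in range(200):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            radial = rng.uniform(0, 0.7) ** (1 / 3)
            center = center_mm + u * radial * (brain_axes - semi - 2.0)
            mask = _ellipsoid_mask(shape, spacing, center, semi)
            if not mask.any():
                continue
            if mask.sum() and not (gt & mask).any() and brain[mask].all():
                # 1-voxel separation so neighbouring lesions stay distinct
                dil = ndimage.binary_dilation(mask, np.ones((3, 3, 3), bool))
                if not (gt & dil).any():
                    gt |= mask.astype(np.uint8)
                    lesion_specs.append(LesionSpec(tuple(center), tuple(semi), float(vol_cc)))
                    placed = True
                    break
        if not placed:
            raise GenerationError(
                f"could not place a {vol_cc:.4f} cc lesion without overlap"
            )

    # vessels avoid lesions (1 mm margin) so ground truth stays unambiguous
    if n_lesions and gt.any():
        keepout = ndimage.distance_transform_edt(gt == 0, sampling=spacing) <= 1.0
    else:
        keepout = np.zeros(shape, dtype=bool)
    vessels = _draw_vessels(shape, spacing, brain, spec.n_vessels, rng, keepout)

    # hyperintensity: lesions get a soft edge; vessels the same range (bait)
    boost = (spec.lesion_contrast - 1.0) * TISSUE_INTENSITY
    lesion_field = ndimage.gaussian_filter(gt.astype(np.float64), sigma=0.7)
    image += boost * lesion_field
    image[vessels] += boost

    vol = ImageVolume(image, spacing)
    vol, _ = add_bias_field(vol, spec.bias_amplitude, seed=int(rng.integers(0, 2**31 - 1)))
    noisy = vol.data + rng.normal(0, spec.noise_sigma * TISSUE_INTENSITY, size=shape)
    image = np.clip(noisy, 0, None)

    gt_vol = LabelVolume(gt, spacing)
    lesion_set = find_lesions(gt_vol, source="ground_truth")
    lesion_set.specs = lesion_specs
    return ImageVolume(image, spacing), gt_vol, lesion_set
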