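"""Whole-volume prediction and lesion extraction.

Each axial slice is predicted by running the model on every 5-slice stack of
the sliding-window grid and averaging the per-patch probabilities over the
overlaps. The averaged map is thresholded (default 0.5), connected
components are extracted under 26-connectivity in 3D, and components smaller
than a minimum physical volume (default 0.02 cc) are rejected as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .patching import PatchGrid, extract_stack, merge_probabilities
from .volume_io import ImageVolume, LabelVolume, voxel_volume_cc

#: 3x3x3 all-ones structuring element = 26-connectivity
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Lesion:
    id: int
    voxels: np.ndarray  # (n, 3) int array of (z, y, x)
    volume_cc: float
    centroid_mm: tuple[float, float, float]


@dataclass
class LesionSet:
    lesions: list[Lesion]
    source: str  # "ground_truth" or "prediction"
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int] | None = None

    def __len__(self) -> int:
        return len(self.lesions)

    def volumes_cc(self) -> np.ndarray:
        return np.array([l.volume_cc for l in self.lesions])

    def to_mask(self, shape=None) -> LabelVolume:
        shape = shape if shape is not None else self.shape
        data = np.zeros(shape, dtype=np.uint8)
        for les in self.lesions:
            data[tuple(les.voxels.T)] = 1
        return LabelVolume(data, self.spacing)


def predict_volume(
    model, image: ImageVolume, grid: PatchGrid, batch_size: int = 64
) -> ImageVolume:
    """Sliding-window 2.5D inference producing a whole-volume probability map."""
    ns, nr, nc = image.shape
    if grid.patch_size > min(nr, nc):
        raise ValueError(
            f"grid patch {grid.patch_size} larger than slice ({nr}, {nc})"
        )
    prob = np.zeros(image.shape, dtype=np.float64)
    windows = list(grid.windows())
    for z in range(ns):
        stacks = [extract_stack(image, None, z, r, c, grid.patch_size) for r, c in windows]
        preds = []
        for i in range(0, len(stacks), batch_size):
            x = np.stack([s.data for s in stacks[i : i + batch_size]]).astype(np.float32)
            preds.append(model.predict_proba(x))
        preds = np.concatenate(preds)
        prob[z] = merge_probabilities(
            [(r, c, p) for (r, c), p in zip(windows, preds)], nr, nc
        )
    return ImageVolume(prob, image.spacing, image.origin, image.affine)


def binarize(prob: ImageVolume, threshold: float = 0.5) -> LabelVolume:
    """Foreground where probability >= threshold."""
    data = np.asarray(prob.data)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return LabelVolume((data >= threshold).astype(np.uint8), prob.spacing,
                       prob.origin, prob.affine)


def find_lesions(mask: LabelVolume, source: str = "prediction") -> LesionSet:
    """Connected components under 26-connectivity, with physical volumes."""
    labeled, n = ndimage.label(mask.data, structure=STRUCT_26)
    vox_cc = voxel_volume_cc(mask.spacing)
    lesions = []
    objects = ndimage.find_objects(labeled)
    for i, slc in enumerate(objects, start=1):
        coords = np.argwhere(labeled[slc] == i) + [s.start for s in slc]
        centroid = coords.mean(axis=0) * np.array(mask.spacing)
        lesions.append(
            Lesion(i, coords, len(coords) * vox_cc, tuple(centroid))
        )
    return LesionSet(lesions, source, mask.spacing, mask.shape)


def filter_small(ls: LesionSet, min_volume_cc: float = 0.02) -> LesionSet:
    """Reject lesions with volume strictly below the threshold."""
    if min_volume_cc < 0:
        raise ValueError(f"min volume must be >= 0, got {min_volume_cc}")
    kept = [l for l in ls.lesions if l.volume_cc >= min_volume_cc]
    return LesionSet(kept, ls.source, ls.spacing, ls.shape)


def predict_lesions(
    model,
    image: ImageVolume,
    grid: PatchGrid,
    *,
    threshold: float = 0.5,
    min_volume_cc: float = 0.02,
    batch_size: int = 64,
) -> tuple[ImageVolume, LabelVolume, LesionSet]:
    """Full prediction chain: probability map -> mask -> filtered lesions."""
    prob = predict_volume(model, image, grid, batch_size=batch_size)
    mask = binarize(prob, threshold)
    lesions = filter_small(find_lesions(mask), min_volume_cc)
    final_mask = lesions.to_mask(mask.shape)
    return prob, final_mask, lesions
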