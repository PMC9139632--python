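"""2.5D overlapping-patch engine.

A slice is tiled by fixed-size square windows sliding at a stride smaller
than the window, so neighbouring windows overlap and every pixel is seen by
several patches. Each training/inference sample is a stack of five
consecutive axial slices cropped at the same (row, col) window — the
reference slice plus two slices of through-plane context on each side —
while the target is the ground-truth crop on the reference slice only.
At merge time the per-patch probability maps are averaged pixelwise over
all windows covering the pixel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .volume_io import ImageVolume, LabelVolume

CONTEXT_SLICES = 2  # slices of context on each side of the reference slice


@dataclass(frozen=True)
class PatchGrid:
    """Window plan for one slice geometry.

    Offsets start at 0 and advance by ``stride``; when the stride does not
    divide ``extent - patch_size`` a final flush window at
    ``extent - patch_size`` is appended so the slice is fully covered.
    """

    patch_size: int
    stride: int
    row_offsets: tuple[int, ...]
    col_offsets: tuple[int, ...]

    @property
    def patches_per_slice(self) -> int:
        return len(self.row_offsets) * len(self.col_offsets)

    def windows(self) -> Iterator[tuple[int, int]]:
        for r in self.row_offsets:
            for c in self.col_offsets:
                yield r, c


@dataclass
class PatchStack:
    """One 2.5D sample: 5 axial crops plus the reference-slice label crop."""

    data: np.ndarray  # (5, patch, patch)
    reference_slice: int
    row: int
    col: int
    label_crop: np.ndarray  # (patch, patch) uint8

    def __post_init__(self) -> None:
        if self.data.shape[0] != 2 * CONTEXT_SLICES + 1:
            raise ValueError(f"expected 5 channels, got {self.data.shape[0]}")
        if self.label_crop.shape != self.data.shape[1:]:
            raise ValueError("label crop misaligned with patch window")

    @property
    def is_tumor(self) -> bool:
        """Tumor iff the reference-slice crop contains any foreground."""
        return bool(self.label_crop.any())


def _axis_offsets(extent: int, patch_size: int, stride: int) -> tuple[int, ...]:
    offsets = list(range(0, extent - patch_size + 1, stride))
    if offsets[-1] != extent - patch_size:
        offsets.append(extent - patch_size)
    return tuple(offsets)


def plan_grid(rows: int, cols: int, patch_size: int = 128, stride: int = 64) -> PatchGrid:
    """Plan the sliding-window offsets for a rows x cols slice."""
    if patch_size > min(rows, cols):
        raise ValueError(f"patch {patch_size} larger than slice ({rows}, {cols})")
    if not (0 < stride <= patch_size):
        raise ValueError(f"stride must be in (0, patch_size], got {stride}")
    return PatchGrid(
        patch_size,
        stride,
        _axis_offsets(rows, patch_size, stride),
        _axis_offsets(cols, patch_size, stride),
    )


def stack_slice_indices(z: int, n_slices: int) -> list[int]:
    """Channel slice indices z-2..z+2 with edge replication at the borders."""
    return [min(max(i, 0), n_slices - 1) for i in range(z - CONTEXT_SLICES, z + CONTEXT_SLICES + 1)]


def extract_stack(
    image: ImageVolume,
    gt: LabelVolume | None,
    z: int,
    row: int,
    col: int,
    patch_size: int = 128,
) -> PatchStack:
    """Extract one 5-slice stack at window (row, col) on reference slice z."""
    ns, nr, nc = image.shape
    if not (0 <= z < ns):
        raise ValueError(f"slice index {z} outside volume of {ns} slices")
    if not (0 <= row <= nr - patch_size and 0 <= col <= nc - patch_size):
        raise ValueError(f"window ({row}, {col}) falls off the {nr}x{nc} slice")
    idx = stack_slice_indices(z, ns)
    window = (slice(row, row + patch_size), slice(col, col + patch_size))
    data = np.stack([image.data[i][window] for i in idx])
    if gt is None:
        label = np.zeros((patch_size, patch_size), dtype=np.uint8)
    else:
        label = np.asarray(gt.data[z][window], dtype=np.uint8)
    return PatchStack(data, z, row, col, label)


def extract_all(
    image: ImageVolume, gt: LabelVolume | None, grid: PatchGrid
) -> Iterator[PatchStack]:
    """Yield one stack per (slice, row, col) window; count = slices x grid size."""
    if gt is not None and gt.shape != image.shape:
        raise ValueError(f"image {image.shape} and labels {gt.shape} misaligned")
    for z in range(image.shape[0]):
        for row, col in grid.windows():
            yield extract_stack(image, gt, z, row, col, grid.patch_size)


def merge_probabilities(
    patches: Sequence[tuple[int, int, np.ndarray]], rows: int, cols: int
) -> np.ndarray:
    """Average overlapping per-patch probability maps back onto the slice.

    Each output pixel is the arithmetic mean of the predictions of all
    patches covering it; every pixel must be covered at least once.
    """
    acc = np.zeros((rows, cols), dtype=np.float64)
    cover = np.zeros((rows, cols), dtype=np.int32)
    for row, col, prob in patches:
        prob = np.asarray(prob)
        p, q = prob.shape
        if prob.min() < -1e-9 or prob.max() > 1 + 1e-9:
            raise ValueError("probability map values must lie in [0, 1]")
        acc[row : row + p, col : col + q] += prob
        cover[row : row + p, col : col + q] += 1
    if (cover == 0).any():
        n = int((cover == 0).sum())
        raise ValueError(f"{n} pixels not covered by any patch")
    return acc / cover
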