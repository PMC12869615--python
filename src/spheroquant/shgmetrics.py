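"""Forward/backward SHG ratio and fluorescence intensity on paired z-stacks.

The F/B ratio reports on collagen fibril diameter and packing: the forward
stack is divided voxelwise by the backward stack (32-bit float), a mask is
taken from the Li threshold of the pooled forward-stack histogram, and the
median ratio is measured only within that mask.  Voxels with zero backward
signal inside the mask are excluded from the median (their count is
reported) rather than mapped to infinity.

Grouped maximum projections reduce a z-stack in non-overlapping groups of
consecutive slices (a 100-slice stack grouped by 3 yields 33 projections
with the last slice discarded); ``n_keep`` first selects the central n
slices, used to pick the slices closest to the spheroid midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spheroquant import imops
from spheroquant.image import Image2D, ImageStack

__all__ = [
    "SHGStackPair",
    "FBResult",
    "IntensityResult",
    "fb_ratio",
    "max_project_groups",
    "stack_median_intensity",
]


@dataclass(frozen=True)
class SHGStackPair:
    forward: ImageStack
    backward: ImageStack
    region_label: str = ""  # {sphere, cells, far}

    def __post_init__(self) -> None:
        if self.forward.shape != self.backward.shape:
            raise ValueError("forward and backward stacks must match in shape")


@dataclass(frozen=True)
class FBResult:
    median_ratio: float
    mask_fraction: float
    n_slices: int
    n_zero_backward: int  # masked voxels excluded for zero backward signal

    def __post_init__(self) -> None:
        if not 0 < self.mask_fraction <= 1:
            raise ValueError("mask_fraction must be in (0, 1]")


@dataclass(frozen=True)
class IntensityResult:
    per_slice_medians: tuple[float, ...]
    stack_median: float
    mode: str


def fb_ratio(pair: SHGStackPair) -> FBResult:
    """Median forward/backward ratio within the Li mask of the forward stack."""
    fwd = pair.forward.as_array().astype(np.float64)
    bwd = pair.backward.as_array().astype(np.float64)
    masks = imops.auto_threshold(pair.forward, "li", use_stack_histogram=True)
    mask = np.stack([m.pixels for m in masks])
    if not mask.any():
        raise ValueError("no SHG foreground: Li mask is empty")
    valid = mask & (bwd > 0)
    n_zero = int(mask.sum() - valid.sum())
    if not valid.any():
        raise ValueError("no SHG foreground with nonzero backward signal")
    ratio = fwd[valid] / bwd[valid]
    return FBResult(
        median_ratio=float(np.median(ratio)),
        mask_fraction=float(mask.mean()),
        n_slices=len(pair.forward),
        n_zero_backward=n_zero,
    )


def max_project_groups(
    stack: ImageStack, group: int = 3, n_keep: int | None = None
) -> ImageStack:
    """Voxelwise max over non-overlapping groups of consecutive slices.

    Trailing remainder slices are discarded.  ``n_keep`` selects the central
    n slices (closest to the stack midpoint) before grouping.
    """
    if group < 1:
        raise ValueError("group must be >= 1")
    arr = stack.as_array()
    if n_keep is not None:
        if n_keep < 1 or n_keep > len(arr):
            raise ValueError("n_keep out of range")
        start = (len(arr) - n_keep) // 2
        arr = arr[start : start + n_keep]
    if len(arr) < group:
        raise ValueError("stack shorter than one group")
    n_groups = len(arr) // group
    arr = arr[: n_groups * group]
    proj = arr.reshape(n_groups, group, *arr.shape[1:]).max(axis=1)
    return ImageStack.from_array(proj, pixel_size=stack.pixel_size)


def stack_median_intensity(
    stack: ImageStack, mode: str = "median_of_medians"
) -> IntensityResult:
    """Per-slice medians plus a stack summary.

    ``median_of_medians`` (default) is the two-step reduction — the median
    of the per-image medians; ``pooled`` takes the median over all voxels.
    """
    arr = stack.as_array().astype(np.float64)
    per_slice = tuple(float(np.median(s)) for s in arr)
    if mode == "median_of_medians":
        stack_median = float(np.median(per_slice))
    elif mode == "pooled":
        stack_median = float(np.median(arr))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return IntensityResult(
        per_slice_medians=per_slice, stack_median=stack_median, mode=mode
    )
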