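"""White-matter mask construction.

Individual masks are cut from tissue-probability maps at a strict
probability threshold (default 0.90), combined into a group mask by an
at-least-80%-of-subjects overlap rule, and cleaned of deep-brain grey
structures via an integer label volume (e.g. a pre-thresholded
subcortical atlas).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinaryMask", "individual_wm_mask", "group_wm_mask", "exclude_labels"]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean voxel mask on a fixed grid with its voxel-to-world affine."""

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        affine = np.asarray(self.affine, dtype=float)
        if grid.ndim != 3:
            raise ValueError(f"mask grid must be 3-D, got shape {grid.shape}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "affine", affine)

    @property
    def n_true(self) -> int:
        return int(self.grid.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


def individual_wm_mask(
    wm_prob: np.ndarray,
    threshold: float = 0.90,
    affine: np.ndarray | None = None,
) -> BinaryMask:
    """Threshold a WM probability map into a subject-level mask.

    A voxel enters the mask only when its WM probability strictly
    exceeds ``threshold``; the strict inequality is the more rigorous
    reading of a hard 90% cut.
    """
    wm_prob = np.asarray(wm_prob, dtype=float)
    if wm_prob.min() < 0 or wm_prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    grid = wm_prob > threshold
    if not grid.any():
        warnings.warn(
            f"individual WM mask is empty at threshold {threshold}",
            stacklevel=2,
        )
    return BinaryMask(grid, np.eye(4) if affine is None else affine)


def group_wm_mask(masks: list[BinaryMask], overlap: float = 0.80) -> BinaryMask:
    """Intersect subject masks into a group mask by an overlap quorum.

    A voxel is kept iff it is true in at least ``ceil(overlap * n)`` of
    the ``n`` individual masks ("across 80% of the participants" read as
    at-least).
    """
    if not masks:
        raise ValueError("need at least one mask")
    ref = masks[0]
    for i, m in enumerate(masks[1:], start=1):
        if m.shape != ref.shape or not np.allclose(m.affine, ref.affine):
            raise ValueError(f"mask for subject index {i} is not on the reference grid")
    counts = np.sum([m.grid for m in masks], axis=0)
    # small epsilon so 0.8 * 5 does not ceil to 5 through float error
    quorum = math.ceil(overlap * len(masks) - 1e-9)
    return BinaryMask(counts >= quorum, ref.affine)


def exclude_labels(
    mask: BinaryMask, labels: np.ndarray, exclude_ids: set[int]
) -> BinaryMask:
    """Remove voxels carrying any of ``exclude_ids`` in a label volume.

    Used to strip subcortical nuclei (thalamus, putamen, caudate,
    pallidum, accumbens) from the group WM mask so deep grey signal does
    not contaminate WM nodes.
    """
    labels = np.asarray(labels)
    if labels.shape != mask.shape:
        raise ValueError("label volume is not on the mask grid")
    exclude_ids = set(int(i) for i in exclude_ids)
    present = set(np.unique(labels).tolist())
    missing = exclude_ids - present
    if missing:
        warnings.warn(
            f"exclusion ids not present in label volume: {sorted(missing)}",
            stacklevel=2,
        )
    drop = np.isin(labels, sorted(exclude_ids))
    return BinaryMask(mask.grid & ~drop, mask.affine)
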