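"""Random region-growing parcellation of a WM mask into balanced nodes.

The group WM mask is subdivided into N contiguous parcels of
near-uniform size: N seed voxels are drawn uniformly without
replacement, then parcels grow voxel-by-voxel, always extending the
currently smallest parcel that still touches unlabeled mask voxels,
until every reachable voxel is assigned.  Voxels on disconnected mask
islands are attached to the nearest parcel in world space so the output
is always a full partition of the mask.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .masking import BinaryMask

__all__ = ["Parcellation", "region_grow_parcellation", "parcel_report"]


def _structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26 voxel adjacency."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    struct = _structure(connectivity)
    offs = np.argwhere(struct) - 1
    return offs[np.any(offs != 0, axis=1)]


@dataclass(frozen=True)
class Parcellation:
    """Integer label volume: 0 outside the mask, 1..N one parcel each."""

    labels: np.ndarray
    n_nodes: int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    connectivity: int = 26
    seed: int | None = None
    node_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        present = np.unique(labels[labels > 0])
        if self.n_nodes < 1 or not np.array_equal(present, np.arange(1, self.n_nodes + 1)):
            raise ValueError("labels must cover exactly 1..n_nodes, all non-empty")
        object.__setattr__(self, "labels", labels.astype(np.int32))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def mask(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.affine)

    def node_sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_nodes + 1)[1:]


def region_grow_parcellation(
    mask: BinaryMask,
    n_nodes: int,
    connectivity: int = 26,
    seed: int | None = None,
) -> Parcellation:
    """Partition a mask into ``n_nodes`` contiguous, size-balanced parcels.

    Growth rule: at every step the parcel with the smallest current
    voxel count (ties to the lowest node id) claims one voxel chosen
    uniformly at random from its unlabeled frontier.  The
    smallest-volume-first discipline is what keeps final parcel sizes
    near-uniform.  Fully deterministic for a fixed (mask, n_nodes,
    connectivity, seed).
    """
    coords = np.argwhere(mask.grid)
    n_vox = coords.shape[0]
    if n_vox < n_nodes:
        raise ValueError(f"mask has {n_vox} voxels, fewer than n_nodes={n_nodes}")
    rng = np.random.default_rng(seed)

    # flat voxel ids 0..n_vox-1; volume of ids for neighbour lookup
    idx_vol = np.full(mask.shape, -1, dtype=np.int64)
    idx_vol[tuple(coords.T)] = np.arange(n_vox)
    offsets = _neighbor_offsets(connectivity)
    shape = np.asarray(mask.shape)

    neighbors: list[np.ndarray] = []
    for c in coords:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        ids = idx_vol[tuple(pts[ok].T)]
        neighbors.append(ids[ids >= 0])

    labels = np.zeros(n_vox, dtype=np.int32)
    seeds = rng.choice(n_vox, size=n_nodes, replace=False)
    sizes = np.ones(n_nodes + 1, dtype=np.int64)
    frontier: list[set[int]] = [set() for _ in range(n_nodes + 1)]
    for node, v in enumerate(seeds, start=1):
        labels[v] = node
    for node, v in enumerate(seeds, start=1):
        frontier[node].update(int(u) for u in neighbors[v] if labels[u] == 0)

    heap: list[tuple[int, int]] = [(1, node) for node in range(1, n_nodes + 1)]
    heapq.heapify(heap)
    while heap:
        size, node = heapq.heappop(heap)
        if size != sizes[node]:
            continue  # superseded entry
        front = frontier[node]
        pick = -1
        while front:
            cand = tuple(front)[rng.integers(len(front))]
            if labels[cand] == 0:
                pick = cand
                break
            front.discard(cand)  # claimed by another node meanwhile
        if pick < 0:
            continue  # walled in; this node can never grow again
        front.discard(pick)
        labels[pick] = node
        sizes[node] += 1
        front.update(int(u) for u in neighbors[pick] if labels[u] == 0)
        heapq.heappush(heap, (int(sizes[node]), node))

    unreached = np.flatnonzero(labels == 0)
    if unreached.size:
        comp_sizes = _island_sizes(mask, connectivity, unreached, idx_vol)
        warnings.warn(
            f"mask has unreachable islands (sizes {comp_sizes}); "
            "assigning them to the nearest parcel in world space",
            stacklevel=2,
        )
        world = nib_apply_affine(mask.affine, coords)
        tree = cKDTree(world[labels > 0])
        labeled_ids = np.flatnonzero(labels > 0)
        _, nearest = tree.query(world[unreached])
        labels[unreached] = labels[labeled_ids[nearest]]

    vol = np.zeros(mask.shape, dtype=np.int32)
    vol[tuple(coords.T)] = labels
    return Parcellation(
        vol, n_nodes, affine=mask.affine, connectivity=connectivity, seed=seed
    )


def nib_apply_affine(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices to world coordinates through a 4x4 affine."""
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def _island_sizes(
    mask: BinaryMask, connectivity: int, unreached: np.ndarray, idx_vol: np.ndarray
) -> list[int]:
    comp, _ = ndimage.label(mask.grid, structure=_structure(connectivity))
    island_labels = comp[tuple(np.argwhere(idx_vol >= 0)[unreached].T)]
    counts = np.bincount(island_labels)
    return sorted(int(c) for c in counts[1:] if c > 0)


def parcel_report(
    p: Parcellation, atlas: np.ndarray | None = None,
    atlas_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """One row per parcel: size, world centroid, connectedness, atlas name.

    When an integer atlas volume is supplied the parcel is named by the
    modal atlas label over its voxels (a pragmatic rule for attaching a
    tract name to a random parcel).
    """
    struct = _structure(p.connectivity)
    rows = []
    for node in range(1, p.n_nodes + 1):
        inside = p.labels == node
        size = int(inside.sum())
        centroid = nib_apply_affine(p.affine, np.argwhere(inside).mean(axis=0))
        _, n_comp = ndimage.label(inside, structure=struct)
        name = ""
        if atlas is not None:
            vals = atlas[inside]
            vals = vals[vals > 0]
            if vals.size:
                modal = int(np.bincount(vals).argmax())
                name = (atlas_names or {}).get(modal, str(modal))
        rows.append(
            {
                "node": node,
                "size": size,
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "centroid_z": centroid[2],
                "connected": n_comp == 1,
                "atlas_name": name,
            }
        )
    return pd.DataFrame(rows)
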