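"""Contiguity checks for structure masks.

A contiguous contour has a connectivity path from every set voxel to every
other.  Two checks are provided, mirroring two very different costs and blind
spots:

* **Extent check** — per axis, the set of distinct occupied coordinate values
  must fill the whole integer range [min, max] (count == range + 1).  Cheap,
  but it only inspects projections: each axis projection can be gap-free even
  when the 3D structure is disconnected.
* **Region growing** — iterative closure from a seed voxel, repeatedly adding
  every unvisited set voxel within Euclidean distance ``neighbor_radius`` (in
  voxel-index units) of a visited one.  With the default radius sqrt(3) on a
  unit-index grid this is exactly the 26-connectivity component of the seed;
  the mask is contiguous iff the closure visits every voxel.

Radius bands reproduce the standard digital connectivities: [1, sqrt2) -> 6,
[sqrt2, sqrt3) -> 18, [sqrt3, 2) -> 26.

A brute-force connected-components oracle (exhaustive pairwise distances,
no spatial index) is included for independent verification; the k-d tree used
by ``region_grow`` is an internal optimization that must not change results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyMaskError, MaskValidationError
from .mask_core import AXES, StructureMask

__all__ = [
    "SQRT2",
    "SQRT3",
    "ContiguityConfig",
    "ContiguityVerdict",
    "check_extent_contiguity",
    "region_grow",
    "check_region_growing_contiguity",
    "connected_components_oracle",
    "oracle_contiguity_verdict",
]

SQRT2 = math.sqrt(2.0)
SQRT3 = math.sqrt(3.0)

#: additive tolerance on the neighbor radius (coordinates are integers, so any
#: tolerance well below the minimum squared-distance gap is exact)
_RADIUS_TOL = 1e-9


@dataclass(frozen=True)
class ContiguityConfig:
    """Neighbor radius (voxel-index units) and seed rule for region growing."""

    neighbor_radius: float = SQRT3
    seed_rule: str = "lowest_linear_index"

    def __post_init__(self) -> None:
        if not (float(self.neighbor_radius) > 0):
            raise MaskValidationError("neighbor_radius must be > 0")
        if self.seed_rule != "lowest_linear_index":
            raise MaskValidationError(f"unknown seed_rule {self.seed_rule!r}")


@dataclass
class ContiguityVerdict:
    """Outcome of a contiguity check.

    ``contiguous`` is None (with ``empty=True``) for empty masks: an empty
    clinical contour is neither contiguous nor noncontiguous, but always
    reportable — the cohort layer flags it separately.
    """

    method: str
    contiguous: bool | None
    empty: bool = False
    detail: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "contiguous": self.contiguous,
            "empty": self.empty,
            "detail": self.detail,
        }


def check_extent_contiguity(mask: StructureMask) -> ContiguityVerdict:
    """Axis-projection check: every axis's occupied coordinate set must be gap-free.

    Contiguous iff for each axis the number of distinct occupied coordinates
    equals the span (range + 1).  ``gap_positions`` lists the missing
    coordinate values strictly inside [min, max] per axis.
    """
    if mask.is_empty:
        return ContiguityVerdict("extent", None, empty=True)
    idx = mask.voxel_indices()
    detail: dict[str, Any] = {}
    contiguous = True
    for ax, name in enumerate(AXES):
        vals = np.unique(idx[:, ax])
        lo, hi = int(vals[0]), int(vals[-1])
        span = hi - lo + 1
        gaps = np.setdiff1d(np.arange(lo, hi + 1), vals)
        detail[name] = {
            "unique_coordinate_count": int(vals.size),
            "span_voxels": span,
            "gap_positions": [int(g) for g in gaps],
        }
        if gaps.size:
            contiguous = False
    return ContiguityVerdict("extent", contiguous, detail=detail)


def _seed_row(points: np.ndarray, lin: np.ndarray, seed_linear_index: int | None) -> int:
    if seed_linear_index is None:
        return int(np.argmin(lin))
    rows = np.flatnonzero(lin == seed_linear_index)
    if rows.size == 0:
        raise MaskValidationError(
            f"seed linear index {seed_linear_index} is not a set voxel"
        )
    return int(rows[0])


def region_grow(
    mask: StructureMask,
    config: ContiguityConfig | None = None,
    *,
    seed_linear_index: int | None = None,
) -> np.ndarray:
    """Grow the neighbor-radius closure from the seed voxel.

    Returns the sorted linear indices of all visited voxels.  The frontier is
    an explicit queue (no recursion); neighbor lookup uses a k-d tree
    fixed-radius ball query, which on integer coordinates equals exhaustive
    distance comparison.
    """
    if mask.is_empty:
        raise EmptyMaskError("region growing is defined only for non-empty masks")
    config = config or ContiguityConfig()
    idx = mask.voxel_indices()
    points = idx.astype(float)
    lin_rowwise = mask.grid.linearize(idx)  # rows are in x-major (argwhere) order
    seed = _seed_row(points, lin_rowwise, seed_linear_index)

    tree = cKDTree(points)
    radius = float(config.neighbor_radius) + _RADIUS_TOL
    visited = np.zeros(len(points), dtype=bool)
    visited[seed] = True
    frontier = np.array([seed])
    while frontier.size:
        balls = tree.query_ball_point(points[frontier], r=radius)
        neigh = np.unique(np.concatenate([np.asarray(b, dtype=np.intp) for b in balls]))
        new = neigh[~visited[neigh]]
        visited[new] = True
        frontier = new
    return np.sort(lin_rowwise[visited])


def check_region_growing_contiguity(
    mask: StructureMask,
    config: ContiguityConfig | None = None,
    *,
    seed_linear_index: int | None = None,
) -> ContiguityVerdict:
    """Contiguous iff the region-growing closure visits every set voxel."""
    if mask.is_empty:
        return ContiguityVerdict("region_growing", None, empty=True)
    visited = region_grow(mask, config, seed_linear_index=seed_linear_index)
    total = mask.voxel_count
    return ContiguityVerdict(
        "region_growing",
        contiguous=bool(visited.size == total),
        detail={
            "visited_count": int(visited.size),
            "total_count": int(total),
            "seed_linear_index": int(visited[0]) if seed_linear_index is None
            else int(seed_linear_index),
        },
    )


def connected_components_oracle(
    mask: StructureMask, config: ContiguityConfig | None = None
) -> tuple[np.ndarray, list[int]]:
    """Brute-force component labeling by exhaustive pairwise distances.

    Independent verification oracle: no spatial index, just BFS over the
    "within neighbor_radius" relation evaluated by direct distance
    computation (chunked so memory stays O(n * chunk)).  Returns
    ``(labels, component_sizes)`` where ``labels[k]`` is the 0-based component
    of the k-th voxel in x-major (argwhere) order.
    """
    if mask.is_empty:
        raise EmptyMaskError("component labeling is defined only for non-empty masks")
    config = config or ContiguityConfig()
    points = mask.voxel_indices().astype(float)
    n = len(points)
    r2 = (float(config.neighbor_radius) + _RADIUS_TOL) ** 2
    labels = np.full(n, -1, dtype=np.int64)
    comp = 0
    chunk = 256
    for start in range(n):
        if labels[start] != -1:
            continue
        labels[start] = comp
        frontier = np.array([start])
        while frontier.size:
            new_mask = np.zeros(n, dtype=bool)
            for lo in range(0, frontier.size, chunk):
                fr = points[frontier[lo:lo + chunk]]
                d2 = ((fr[:, None, :] - points[None, :, :]) ** 2).sum(axis=-1)
                new_mask |= (d2 <= r2).any(axis=0)
            new = np.flatnonzero(new_mask & (labels == -1))
            labels[new] = comp
            frontier = new
        comp += 1
    sizes = [int((labels == c).sum()) for c in range(comp)]
    return labels, sizes


def oracle_contiguity_verdict(
    mask: StructureMask, config: ContiguityConfig | None = None
) -> ContiguityVerdict:
    """Verdict form of the brute-force oracle (contiguous iff one component)."""
    if mask.is_empty:
        return ContiguityVerdict("oracle", None, empty=True)
    _, sizes = connected_components_oracle(mask, config)
    return ContiguityVerdict(
        "oracle",
        contiguous=len(sizes) == 1,
        detail={"component_count": len(sizes), "component_sizes": sizes},
    )
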