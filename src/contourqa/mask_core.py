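"""Binary structure masks on a regular voxel grid: RLE codec and geometric metrics.

A radiotherapy structure (region of interest, ROI) is represented as a 3D binary
mask on a grid with anisotropic physical spacing.  Axis semantics are fixed
throughout the package:

* x = left-right (LR), ``x_spacing`` mm per voxel,
* y = anterior-posterior (AP),
* z = inferior-superior (IS), typically the CT slice axis.

The linear index of voxel ``(x, y, z)`` is ``z*(x_dim*y_dim) + y*x_dim + x``
(x varies fastest).  Run-length encoding stores the 0-based linear indices at
which the mask value changes; consecutive transition pairs are half-open runs
``[t0, t1), [t2, t3), ...`` of set voxels.  Reconstruction of (x, y, z) triples
from a linear index i inverts the linearization::

    z = i // (x_dim * y_dim)
    y = (i - z * x_dim * y_dim) // x_dim
    x = i - z * x_dim * y_dim - y * x_dim

Geometric metrics defined here (volume, per-axis extent, per-slice extent,
extent ratios) are the features consumed by the cohort outlier models.
"Extent" is the coordinate range max - min, exposed both in voxels (``range_voxels``,
plus ``span_voxels = range + 1``) and in millimetres (``range_mm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import EmptyMaskError, MaskValidationError

__all__ = [
    "AXES",
    "VoxelGrid",
    "StructureMask",
    "RleMask",
    "ExtentSummary",
    "SliceExtentProfile",
    "ExtentRatios",
    "rle_encode",
    "rle_decode",
    "mask_to_indices",
    "linearize_indices",
    "compute_volume",
    "compute_extent",
    "slice_extents",
    "extent_ratios",
]

#: axis names in (x, y, z) order
AXES = ("lr", "ap", "is")


@dataclass(frozen=True)
class VoxelGrid:
    """Grid dimensions (voxel counts) and physical spacing (mm per voxel)."""

    x_dim: int
    y_dim: int
    z_dim: int
    x_spacing: float = 1.0
    y_spacing: float = 1.0
    z_spacing: float = 1.0

    def __post_init__(self) -> None:
        for name in ("x_dim", "y_dim", "z_dim"):
            v = getattr(self, name)
            if int(v) != v or int(v) < 1:
                raise MaskValidationError(f"{name} must be a positive integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        for name in ("x_spacing", "y_spacing", "z_spacing"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise MaskValidationError(f"{name} must be a positive finite number, got {v!r}")
            object.__setattr__(self, name, v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x_dim, self.y_dim, self.z_dim)

    @property
    def dims(self) -> np.ndarray:
        return np.array(self.shape, dtype=np.int64)

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.x_spacing, self.y_spacing, self.z_spacing])

    @property
    def n_voxels(self) -> int:
        return self.x_dim * self.y_dim * self.z_dim

    @property
    def voxel_volume_mm3(self) -> float:
        return self.x_spacing * self.y_spacing * self.z_spacing

    def linearize(self, indices: np.ndarray) -> np.ndarray:
        """Linear index of ``(x, y, z)`` triples (n, 3) under x-fastest ordering."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.int64))
        if idx.shape[-1] != 3:
            raise MaskValidationError("indices must have shape (n, 3)")
        if np.any(idx < 0) or np.any(idx >= self.dims):
            raise MaskValidationError("voxel indices out of grid bounds")
        return idx[:, 2] * (self.x_dim * self.y_dim) + idx[:, 1] * self.x_dim + idx[:, 0]

    def delinearize(self, linear: np.ndarray) -> np.ndarray:
        """Recover ``(x, y, z)`` triples from linear indices.

        This is the index-reconstruction step applied to every set voxel of an
        RLE mask: z from integer division by the slice size, y from the
        remainder divided by the row length, x from what is left.
        """
        lin = np.asarray(linear, dtype=np.int64)
        if np.any(lin < 0) or np.any(lin >= self.n_voxels):
            raise MaskValidationError("linear indices out of grid bounds")
        plane = self.x_dim * self.y_dim
        z = lin // plane
        rem = lin - z * plane
        y = rem // self.x_dim
        x = rem - y * self.x_dim
        return np.stack([x, y, z], axis=-1)

    def same_spacing(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and bool(
            np.all(np.abs(self.spacing - other.spacing) <= tol)
        )


@dataclass
class StructureMask:
    """One ROI's binary mask bound to a :class:`VoxelGrid`.

    ``data`` has shape ``grid.shape`` = (x_dim, y_dim, z_dim) and dtype bool;
    ``data.ravel(order="F")`` is exactly the x-fastest linearization.
    """

    grid: VoxelGrid
    data: np.ndarray
    roi_name: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.shape != self.grid.shape:
            raise MaskValidationError(
                f"mask array shape {arr.shape} does not match grid dims {self.grid.shape}"
            )
        self.data = arr.astype(bool, copy=False)

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls, grid: VoxelGrid, roi_name: str | None = None) -> "StructureMask":
        return cls(grid, np.zeros(grid.shape, dtype=bool), roi_name)

    @classmethod
    def from_linear_indices(
        cls, grid: VoxelGrid, linear: Iterable[int], roi_name: str | None = None
    ) -> "StructureMask":
        flat = np.zeros(grid.n_voxels, dtype=bool)
        lin = np.asarray(list(linear) if not isinstance(linear, np.ndarray) else linear,
                         dtype=np.int64)
        if lin.size and (lin.min() < 0 or lin.max() >= grid.n_voxels):
            raise MaskValidationError("linear indices out of grid bounds")
        flat[lin] = True
        return cls(grid, flat.reshape(grid.shape, order="F"), roi_name)

    @classmethod
    def from_voxels(
        cls, grid: VoxelGrid, voxels: Iterable[tuple[int, int, int]],
        roi_name: str | None = None,
    ) -> "StructureMask":
        vox = np.asarray(list(voxels), dtype=np.int64).reshape(-1, 3)
        if vox.size == 0:
            return cls.empty(grid, roi_name)
        return cls.from_linear_indices(grid, grid.linearize(vox), roi_name)

    # -- basics -------------------------------------------------------
    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    @property
    def linear_indices(self) -> np.ndarray:
        """Sorted linear indices of the set voxels."""
        return np.flatnonzero(self.data.ravel(order="F"))

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) array of set-voxel (x, y, z) coordinates."""
        return np.argwhere(self.data)

    def equals(self, other: "StructureMask", spacing_tol: float = 1e-6) -> bool:
        return self.grid.same_spacing(other.grid, spacing_tol) and np.array_equal(
            self.data, other.data
        )


@dataclass
class RleMask:
    """Run-length-encoded mask: strictly increasing transition indices, even count.

    Transitions live in ``[0, n_voxels]``; the closing transition of a run that
    touches the final voxel equals ``n_voxels`` (half-open runs).
    """

    grid: VoxelGrid
    transitions: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, dtype=np.int64).ravel()
        if t.size % 2 != 0:
            raise MaskValidationError(
                f"transition count must be even, got {t.size} (runs are half-open pairs)"
            )
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise MaskValidationError("transitions must be strictly increasing")
            if t[0] < 0 or t[-1] > self.grid.n_voxels:
                raise MaskValidationError(
                    f"transitions must lie in [0, {self.grid.n_voxels}]"
                )
        self.transitions = t

    @property
    def voxel_count(self) -> int:
        if self.transitions.size == 0:
            return 0
        pairs = self.transitions.reshape(-1, 2)
        return int((pairs[:, 1] - pairs[:, 0]).sum())

    def set_linear_indices(self) -> np.ndarray:
        """Expand the runs into the sorted linear indices of all set voxels."""
        if self.transitions.size == 0:
            return np.array([], dtype=np.int64)
        pairs = self.transitions.reshape(-1, 2)
        lengths = pairs[:, 1] - pairs[:, 0]
        total = int(lengths.sum())
        offsets = np.arange(total) - np.repeat(
            np.concatenate([[0], np.cumsum(lengths)[:-1]]), lengths
        )
        return np.repeat(pairs[:, 0], lengths) + offsets


def rle_encode(mask: StructureMask | np.ndarray, grid: VoxelGrid | None = None) -> RleMask:
    """Run-length encode a dense binary mask.

    Transitions mark every 0->1 and 1->0 boundary of the x-fastest linearized
    sequence; a run reaching the last voxel closes at ``n_voxels``.
    """
    if isinstance(mask, StructureMask):
        grid = mask.grid
        arr = mask.data
    else:
        if grid is None:
            raise MaskValidationError("rle_encode needs a VoxelGrid when given a bare array")
        arr = np.asarray(mask)
        if arr.shape != grid.shape:
            raise MaskValidationError(
                f"mask array shape {arr.shape} does not match grid dims {grid.shape}"
            )
        arr = arr.astype(bool)
    flat = arr.ravel(order="F")
    padded = np.concatenate([[False], flat, [False]]).astype(np.int8)
    transitions = np.flatnonzero(np.diff(padded))
    return RleMask(grid, transitions)


def rle_decode(rle: RleMask) -> np.ndarray:
    """Decode to a dense bool array of shape ``grid.shape``; inverse of encode.

    Every voxel strictly inside a run pair is filled, not just the transition
    points themselves.
    """
    n = rle.grid.n_voxels
    delta = np.zeros(n + 1, dtype=np.int8)
    if rle.transitions.size:
        pairs = rle.transitions.reshape(-1, 2)
        delta[pairs[:, 0]] += 1
        delta[pairs[:, 1]] -= 1
    flat = np.cumsum(delta[:-1]) > 0
    return flat.reshape(rle.grid.shape, order="F")


def mask_to_indices(rle: RleMask) -> np.ndarray:
    """All set-voxel (x, y, z) triples of an RLE mask, via index reconstruction.

    Covers every voxel inside the runs, not only the stored transition points.
    Returns an (n, 3) int array sorted by linear index.
    """
    lin = rle.set_linear_indices()
    if lin.size == 0:
        return np.empty((0, 3), dtype=np.int64)
    return rle.grid.delinearize(lin)


def linearize_indices(indices: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Inverse of :func:`mask_to_indices` for round-trip checks."""
    return grid.linearize(indices)


# ---------------------------------------------------------------------------
# geometric metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtentSummary:
    """Per-axis occupied-coordinate extrema, in (lr, ap, is) = (x, y, z) order."""

    min_index: tuple[int, int, int]
    max_index: tuple[int, int, int]
    range_voxels: tuple[int, int, int]   # max - min, the subtraction definition
    span_voxels: tuple[int, int, int]    # range + 1
    range_mm: tuple[float, float, float]

    @property
    def lr_range_mm(self) -> float:
        return self.range_mm[0]

    @property
    def ap_range_mm(self) -> float:
        return self.range_mm[1]

    @property
    def is_range_mm(self) -> float:
        return self.range_mm[2]


@dataclass(frozen=True)
class SliceExtentProfile:
    """In-plane extents per occupied IS slice, and their spread across slices.

    Only occupied slices appear.  ``*_range_of_ranges_mm`` is max - min of the
    per-slice range over occupied slices (0 when a single slice is occupied);
    it is the feature the slice-based extent outlier model thresholds.
    """

    z_indices: np.ndarray
    lr_range_mm: np.ndarray
    ap_range_mm: np.ndarray
    lr_range_of_ranges_mm: float
    ap_range_of_ranges_mm: float


@dataclass(frozen=True)
class ExtentRatios:
    """Dimensionless shape descriptors from the three mm extents.

    ``defined`` is False when any axis range is zero (e.g. a single-voxel or
    single-slice mask); the cohort models treat undefined ratios as automatic
    outliers rather than raising.
    """

    lr_over_ap: float
    lr_over_is: float
    ap_over_is: float
    defined: bool = True


def compute_volume(mask: StructureMask) -> float:
    """Total ROI volume in mm^3 (voxel count times voxel volume); 0 if empty."""
    return mask.voxel_count * mask.grid.voxel_volume_mm3


def compute_extent(mask: StructureMask) -> ExtentSummary:
    """Per-axis extent (max index minus min index) of the occupied voxels."""
    if mask.is_empty:
        raise EmptyMaskError("extent is defined only for non-empty masks")
    idx = mask.voxel_indices()
    mins = idx.min(axis=0)
    maxs = idx.max(axis=0)
    rng = maxs - mins
    return ExtentSummary(
        min_index=tuple(int(v) for v in mins),
        max_index=tuple(int(v) for v in maxs),
        range_voxels=tuple(int(v) for v in rng),
        span_voxels=tuple(int(v) + 1 for v in rng),
        range_mm=tuple(float(v) for v in rng * mask.grid.spacing),
    )


def slice_extents(mask: StructureMask) -> SliceExtentProfile:
    """LR/AP extent (mm) of every occupied IS slice, plus their spreads."""
    if mask.is_empty:
        raise EmptyMaskError("slice extents are defined only for non-empty masks")
    grid = mask.grid
    occupied = np.flatnonzero(mask.data.any(axis=(0, 1)))
    lr = np.empty(occupied.size)
    ap = np.empty(occupied.size)
    for k, z in enumerate(occupied):
        xs, ys = np.nonzero(mask.data[:, :, z])
        lr[k] = (xs.max() - xs.min()) * grid.x_spacing
        ap[k] = (ys.max() - ys.min()) * grid.y_spacing
    return SliceExtentProfile(
        z_indices=occupied,
        lr_range_mm=lr,
        ap_range_mm=ap,
        lr_range_of_ranges_mm=float(lr.max() - lr.min()),
        ap_range_of_ranges_mm=float(ap.max() - ap.min()),
    )


def extent_ratios(extent: ExtentSummary) -> ExtentRatios:
    """LR/AP, LR/IS and AP/IS ratios of the mm extents.

    Returns an undefined marker (``defined=False``, NaN values) when any axis
    range is zero, instead of raising, so cohort models can auto-flag.
    """
    lr, ap, is_ = extent.range_mm
    if min(lr, ap, is_) <= 0.0:
        return ExtentRatios(float("nan"), float("nan"), float("nan"), defined=False)
    return ExtentRatios(lr / ap, lr / is_, ap / is_, defined=True)
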