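"""Seeded synthetic organ phantoms with controllable defect injection.

The generator emulates cohorts of organ-shaped binary masks on clinically
plausible anisotropic grids (default 64x64x80 voxels at 1x1x2 mm; long thin
cord-like organs use 32x32x120).  Every phantom is solid, 26-connected and
keeps a >=1-voxel margin to the grid boundary before defect injection.  All
randomness flows from one integer seed through numpy's PCG64 generator
(recorded in the cohort manifest header), so identical seeds give
byte-identical cohorts.

Defect kinds mirror the contouring failure modes the integrity checks target:

* ``missing_slices``  — interior IS slices deleted; breaks both contiguity checks.
* ``detached_island`` — a small voxel island placed > sqrt(3) from the body;
  breaks region growing, and the extent check only if it leaves an axis gap
  (default placement is inside the bounding box, where it does not).
* ``frame_shift``     — one slice's contour also appears translated in-plane
  (union of the slice with its shifted copy), inflating the slice-extent
  range-of-ranges while both contiguity checks still pass.
* ``interior_void``   — a hollow carved strictly inside; contiguity preserved.
* ``slice_oblong``    — one slice dilated along one in-plane axis.
* ``flat_low_volume`` — cohort-level bladder defect: a flattened, low-volume
  (empty-bladder) phantom substituted for a full one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DefectError, GeometryError, MaskValidationError
from .mask_core import StructureMask, VoxelGrid
from .mask_io import CohortManifest, read_manifest, write_mask, write_manifest

__all__ = [
    "ORGANS",
    "COHORT_ORGANS",
    "DEFECT_KINDS",
    "DETECTORS_BY_DEFECT",
    "PhantomSpec",
    "DefectSpec",
    "default_grid",
    "generate_phantom",
    "inject_defect",
    "generate_cohort",
]

ORGANS = (
    "bladder_full",
    "bladder_empty",
    "femoral_ball",
    "femoral_ball_shaft",
    "spinal_cord",
    "rectum",
    "prostate",
    "brainstem_like",
)

#: organ names accepted by generate_cohort ("bladder" = full bladders with
#: flat/empty phantoms as the plantable defect)
COHORT_ORGANS = (
    "bladder",
    "spinal_cord",
    "rectum",
    "femoral_ball",
    "femoral_ball_shaft",
    "prostate",
    "brainstem_like",
)

DEFECT_KINDS = (
    "missing_slices",
    "detached_island",
    "frame_shift",
    "interior_void",
    "slice_oblong",
    "flat_low_volume",
)

#: which detectors are expected to fire per defect kind (used for the
#: ground-truth confusion matrices); slice_oblong inflates one in-plane axis
#: only, so it needs the slice-extent model's OR combination.
DETECTORS_BY_DEFECT = {
    "missing_slices": ("extent", "region_growing"),
    "detached_island": ("region_growing",),
    "frame_shift": ("slice_extent",),
    "interior_void": (),
    "slice_oblong": ("slice_extent",),
    "flat_low_volume": ("bladder",),
}

ORGAN_ROI = {
    "bladder_full": "bladder",
    "bladder_empty": "bladder",
    "bladder": "bladder",
    "femoral_ball": "femoral_head_left",
    "femoral_ball_shaft": "femoral_head_left",
    "spinal_cord": "spinal_cord",
    "rectum": "rectum",
    "prostate": "prostate",
    "brainstem_like": "brainstem",
}

#: shape-parameter jitter ranges (uniform), recorded in manifest headers
JITTER_RANGES = {
    "bladder_full": {"scale": [0.85, 1.15], "center_jitter_mm": [-2, 2],
                     "elongation": [0.10, 0.25]},
    "bladder_empty": {"semi_axes_mm": [[17, 19], [11, 13], [3, 5]],
                      "center_jitter_mm": [-2, 2]},
    "femoral_ball": {"ball_radius_mm": [13, 16], "center_jitter_mm": [-2, 2]},
    "femoral_ball_shaft": {"ball_radius_mm": [13, 16], "center_jitter_mm": [-2, 2],
                           "shaft_length_factor": 6.0, "shaft_radius_factor": 0.5},
    "spinal_cord": {"radius_mm": [4.5, 5.5], "drift_amp_mm": [2, 3],
                    "drift_phase": [0.0, 6.283185307179586]},
    "rectum": {"radius_mm": [7, 9], "curve_amp_mm": [6, 10],
               "center_jitter_mm": [-2, 2]},
    "prostate": {"scale": [0.9, 1.1], "center_jitter_mm": [-2, 2]},
    "brainstem_like": {"radius_top_mm": [10, 12], "radius_bottom_mm": [5, 7],
                       "center_jitter_mm": [-2, 2]},
}

_DEFAULT_MIX = {
    "bladder": {"flat_low_volume": 1.0},
    "spinal_cord": {"frame_shift": 1.0},
    "rectum": {"missing_slices": 0.6, "detached_island": 0.4},
}

_SQRT3 = np.sqrt(3.0)
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2, "lr": 0, "ap": 1, "is": 2}


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic organ."""

    organ: str
    grid: VoxelGrid | None = None
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise MaskValidationError(f"unknown organ {self.organ!r}; choose from {ORGANS}")


@dataclass
class DefectSpec:
    """One planted defect; the ground-truth label derives from ``kind``."""

    kind: str
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise MaskValidationError(f"unknown defect kind {self.kind!r}")


def default_grid(organ: str) -> VoxelGrid:
    """Clinically plausible desk-scale grid per organ."""
    if organ in ("spinal_cord", "brainstem_like"):
        return VoxelGrid(32, 32, 120, 1.0, 1.0, 2.0)
    return VoxelGrid(64, 64, 80, 1.0, 1.0, 2.0)


# ---------------------------------------------------------------------------
# shape primitives (voxel centers at index * spacing, all in mm)
# ---------------------------------------------------------------------------

def _coords(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        np.arange(grid.x_dim) * grid.x_spacing,
        np.arange(grid.y_dim) * grid.y_spacing,
        np.arange(grid.z_dim) * grid.z_spacing,
    )


def _grid_center(grid: VoxelGrid) -> np.ndarray:
    return (grid.dims - 1) / 2.0 * grid.spacing


def _ellipsoid(grid: VoxelGrid, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    xs, ys, zs = _coords(grid)
    u = ((xs - center[0]) / semi[0]) ** 2
    v = ((ys - center[1]) / semi[1]) ** 2
    w = ((zs - center[2]) / semi[2]) ** 2
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0


def _tube(
    grid: VoxelGrid,
    z_slices: np.ndarray,
    cx_mm: np.ndarray,
    cy_mm: np.ndarray,
    radius_mm: np.ndarray | float,
) -> np.ndarray:
    """Stack of filled in-plane disks with per-slice centers and radii."""
    xs, ys, _ = _coords(grid)
    r = np.broadcast_to(np.asarray(radius_mm, dtype=float), z_slices.shape)
    dx2 = (xs[:, None] - cx_mm[None, :]) ** 2          # (X, nz)
    dy2 = (ys[:, None] - cy_mm[None, :]) ** 2          # (Y, nz)
    disks = dx2[:, None, :] + dy2[None, :, :] <= r[None, None, :] ** 2
    data = np.zeros(grid.shape, dtype=bool)
    data[:, :, z_slices] = disks
    return data


# ---------------------------------------------------------------------------
# organ builders
# ---------------------------------------------------------------------------

def _bladder_full(grid, rng, scale=None, elong_axis=None, elong=0.0):
    center = _grid_center(grid) + rng.uniform(-2, 2, size=3)
    if scale is None:
        scale = rng.uniform(0.85, 1.15)
    semi = np.full(3, 20.0 * scale)
    if elong_axis is not None:
        ax = _AXIS_INDEX[elong_axis]
        semi[ax] *= 1.0 + elong
        semi[[a for a in range(3) if a != ax]] /= np.sqrt(1.0 + elong)
    return _ellipsoid(grid, center, semi)


def _bladder_empty(grid, rng):
    center = _grid_center(grid) + rng.uniform(-2, 2, size=3)
    semi = np.array([18.0, 12.0, 4.0]) + rng.uniform(-1, 1, size=3)
    return _ellipsoid(grid, center, semi)


def _femoral_ball(grid, rng, ball_radius_mm=None):
    if ball_radius_mm is None:
        ball_radius_mm = rng.uniform(13.0, 16.0)
    c = _grid_center(grid)
    center = np.array([c[0], c[1], 126.0]) + rng.uniform(-2, 2, size=3)
    return _ellipsoid(grid, center, np.full(3, ball_radius_mm)), center, ball_radius_mm


def _femoral_ball_only(grid, rng, ball_radius_mm=None):
    data, _, _ = _femoral_ball(grid, rng, ball_radius_mm)
    return data


def _femoral_ball_shaft(grid, rng, ball_radius_mm=None, shaft_length_factor=6.0,
                        shaft_radius_factor=0.5):
    data, center, r = _femoral_ball(grid, rng, ball_radius_mm)
    xs, ys, zs = _coords(grid)
    shaft_r = shaft_radius_factor * r
    z_top = center[2]
    z_bot = center[2] - (shaft_length_factor + 1.0) * r
    in_z = (zs >= z_bot) & (zs <= z_top)
    dx2 = (xs - center[0])[:, None] ** 2
    dy2 = (ys - center[1])[None, :] ** 2
    disk = dx2 + dy2 <= shaft_r ** 2
    data |= disk[:, :, None] & in_z[None, None, :]
    return data


def _spinal_cord(grid, rng, radius_mm=None, drift_amp_mm=None, drift_phase=None):
    if radius_mm is None:
        radius_mm = rng.uniform(4.5, 5.5)
    if drift_amp_mm is None:
        drift_amp_mm = rng.uniform(2.0, 3.0)
    if drift_phase is None:
        drift_phase = rng.uniform(0.0, 2 * np.pi)
    c = _grid_center(grid)
    z_slices = np.arange(4, grid.z_dim - 4)
    z_mm = z_slices * grid.z_spacing
    wavelength_mm = 120.0  # per-slice centroid drift stays well below 1 voxel
    cx = c[0] + drift_amp_mm * np.sin(2 * np.pi * z_mm / wavelength_mm + drift_phase)
    cy = c[1] + 0.6 * drift_amp_mm * np.sin(
        2 * np.pi * z_mm / wavelength_mm + drift_phase + np.pi / 2
    )
    return _tube(grid, z_slices, cx, cy, radius_mm)


def _rectum(grid, rng, radius_mm=None, curve_amp_mm=None):
    if radius_mm is None:
        radius_mm = rng.uniform(7.0, 9.0)
    if curve_amp_mm is None:
        curve_amp_mm = rng.uniform(6.0, 10.0)
    jitter = rng.uniform(-2, 2, size=2)
    c = _grid_center(grid)
    z_slices = np.arange(6, grid.z_dim - 6)
    z_mm = z_slices * grid.z_spacing
    t = (z_mm - z_mm[0]) / (z_mm[-1] - z_mm[0])
    cx = np.full_like(t, c[0] + jitter[0])
    cy = c[1] + jitter[1] + curve_amp_mm * np.sin(np.pi * t)
    return _tube(grid, z_slices, cx, cy, radius_mm)


def _prostate(grid, rng, scale=None):
    center = _grid_center(grid) + rng.uniform(-2, 2, size=3)
    if scale is None:
        scale = rng.uniform(0.9, 1.1)
    return _ellipsoid(grid, center, scale * np.array([20.0, 17.0, 15.0]))


def _brainstem_like(grid, rng, radius_top_mm=None, radius_bottom_mm=None):
    if radius_top_mm is None:
        radius_top_mm = rng.uniform(10.0, 12.0)
    if radius_bottom_mm is None:
        radius_bottom_mm = rng.uniform(5.0, 7.0)
    jitter = rng.uniform(-2, 2, size=2)
    c = _grid_center(grid)
    z_slices = np.arange(10, grid.z_dim - 10)
    t = (z_slices - z_slices[0]) / (z_slices[-1] - z_slices[0])
    radii = radius_bottom_mm + (radius_top_mm - radius_bottom_mm) * t
    cx = np.full(z_slices.shape, c[0] + jitter[0])
    cy = np.full(z_slices.shape, c[1] + jitter[1])
    return _tube(grid, z_slices, cx, cy, radii)


_BUILDERS = {
    "bladder_full": _bladder_full,
    "bladder_empty": _bladder_empty,
    "femoral_ball": _femoral_ball_only,
    "femoral_ball_shaft": _femoral_ball_shaft,
    "spinal_cord": _spinal_cord,
    "rectum": _rectum,
    "prostate": _prostate,
    "brainstem_like": _brainstem_like,
}


def generate_phantom(spec: PhantomSpec) -> StructureMask:
    """Deterministically build one organ phantom from its spec."""
    grid = spec.grid or default_grid(spec.organ)
    rng = np.random.default_rng(spec.rng_seed)
    data = _BUILDERS[spec.organ](grid, rng, **spec.params)
    mask = StructureMask(grid, data, roi_name=ORGAN_ROI[spec.organ])
    if mask.is_empty:
        raise GeometryError(f"{spec.organ} phantom produced an empty mask on grid {grid.shape}")
    idx = mask.voxel_indices()
    if np.any(idx.min(axis=0) < 1) or np.any(idx.max(axis=0) > grid.dims - 2):
        raise GeometryError(
            f"{spec.organ} phantom does not keep a 1-voxel margin inside grid {grid.shape}"
        )
    return mask


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

def _occupied_slices(data: np.ndarray, axis: int) -> np.ndarray:
    other = tuple(a for a in range(3) if a != axis)
    return np.flatnonzero(data.any(axis=other))


def _inject_missing_slices(data, rng, axis="z", slice_indices=None, n_slices=1):
    ax = _AXIS_INDEX[axis]
    occ = _occupied_slices(data, ax)
    interior = occ[(occ > occ[0]) & (occ < occ[-1])]
    if slice_indices is None:
        if interior.size < n_slices:
            raise DefectError("mask has too few interior slices for missing_slices")
        start = rng.integers(0, interior.size - n_slices + 1)
        slice_indices = list(interior[start:start + n_slices])
    slice_indices = [int(s) for s in slice_indices]
    for s in slice_indices:
        if s not in occ:
            raise DefectError(f"missing_slices index {s} is not an occupied slice")
        if s <= occ[0] or s >= occ[-1]:
            raise DefectError(f"missing_slices index {s} is not interior")
    out = data.copy()
    sl = [slice(None)] * 3
    for s in slice_indices:
        sl[ax] = s
        out[tuple(sl)] = False
    return out, {"axis": axis, "slice_indices": slice_indices}


def _inject_detached_island(data, rng, island_size=2, placement="corner", gap_voxels=3):
    idx = np.argwhere(data)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    s = int(island_size)
    out = data.copy()
    if placement == "corner":
        # anchor positions inside the bounding box where every island voxel is
        # > sqrt(3) from the body: axis coordinate sets stay complete, so only
        # region growing can see this defect
        edt = ndimage.distance_transform_edt(~data)
        ok = edt > _SQRT3 + 1e-6
        anchor_ok = np.ones(np.maximum(np.array(data.shape) - s + 1, 1), dtype=bool)
        for dx in range(s):
            for dy in range(s):
                for dz in range(s):
                    anchor_ok &= ok[dx:dx + anchor_ok.shape[0],
                                    dy:dy + anchor_ok.shape[1],
                                    dz:dz + anchor_ok.shape[2]]
        bbox = np.zeros_like(anchor_ok)
        blo = lo
        bhi = np.maximum(hi - s + 1, blo)
        bbox[blo[0]:bhi[0] + 1, blo[1]:bhi[1] + 1, blo[2]:bhi[2] + 1] = True
        cand = np.argwhere(anchor_ok & bbox)
        if cand.size == 0:
            raise DefectError("no axis-complete position > sqrt(3) from the body")
        d = np.abs(cand - lo).sum(axis=1)
        pick = cand[np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], d))[0]]
    elif placement == "outside":
        # beyond the bounding box along +x with an empty gap: leaves an axis
        # coordinate gap, so the extent check fires too
        pick = np.array([hi[0] + 1 + gap_voxels, (lo[1] + hi[1]) // 2, (lo[2] + hi[2]) // 2])
        if pick[0] + s > data.shape[0]:
            raise DefectError("no room outside the bounding box for a detached island")
    else:
        raise DefectError(f"unknown detached_island placement {placement!r}")
    out[pick[0]:pick[0] + s, pick[1]:pick[1] + s, pick[2]:pick[2] + s] = True
    # the island must truly be detached
    island = np.argwhere(out & ~data)
    d2 = ((island[:, None, :].astype(float) - idx[None, :, :]) ** 2).sum(-1)
    if d2.min() <= 3.0 + 1e-9:
        raise DefectError("detached island placement touches the body")
    return out, {"anchor": [int(v) for v in pick], "island_size": s,
                 "placement": placement}


def _inject_frame_shift(data, rng, slice_index=None, shift=(5, 5)):
    occ = _occupied_slices(data, 2)
    interior = occ[(occ > occ[0]) & (occ < occ[-1])]
    if slice_index is None:
        if interior.size == 0:
            raise DefectError("mask has no interior slice for frame_shift")
        slice_index = int(interior[rng.integers(0, interior.size)])
    if slice_index not in occ:
        raise DefectError(f"frame_shift slice {slice_index} is not occupied")
    plane = data[:, :, slice_index]
    xs, ys = np.nonzero(plane)
    # shift toward the grid center so the displaced copy stays in bounds
    dx = int(shift[0]) * (1 if xs.mean() <= data.shape[0] / 2 else -1)
    dy = int(shift[1]) * (1 if ys.mean() <= data.shape[1] / 2 else -1)
    nx, ny = xs + dx, ys + dy
    if nx.min() < 0 or ny.min() < 0 or nx.max() >= data.shape[0] or ny.max() >= data.shape[1]:
        raise DefectError("frame_shift would push the contour out of the grid")
    out = data.copy()
    out[nx, ny, slice_index] = True
    return out, {"slice_index": int(slice_index), "shift": [dx, dy]}


def _inject_interior_void(data, rng, void_radius_voxels=2.0):
    edt = ndimage.distance_transform_edt(data)
    if edt.max() <= void_radius_voxels + 1.0:
        raise DefectError("mask interior too thin for an interior void")
    center = np.unravel_index(int(np.argmax(edt)), data.shape)
    xs = np.arange(data.shape[0])[:, None, None]
    ys = np.arange(data.shape[1])[None, :, None]
    zs = np.arange(data.shape[2])[None, None, :]
    ball = ((xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2
            <= void_radius_voxels ** 2)
    out = data & ~ball
    if out.sum() == data.sum():
        raise DefectError("interior void removed no voxels")
    return out, {"center": [int(v) for v in center], "radius_voxels": void_radius_voxels}


def _inject_slice_oblong(data, rng, slice_index=None, axis="x", extra_voxels=5):
    occ = _occupied_slices(data, 2)
    interior = occ[(occ > occ[0]) & (occ < occ[-1])]
    if slice_index is None:
        if interior.size == 0:
            raise DefectError("mask has no interior slice for slice_oblong")
        slice_index = int(interior[rng.integers(0, interior.size)])
    if slice_index not in occ:
        raise DefectError(f"slice_oblong slice {slice_index} is not occupied")
    ax = _AXIS_INDEX[axis]
    if ax == 2:
        raise DefectError("slice_oblong axis must be in-plane (x or y)")
    structure = np.zeros((3, 3), dtype=bool)
    if ax == 0:
        structure[:, 1] = True
    else:
        structure[1, :] = True
    out = data.copy()
    out[:, :, slice_index] = ndimage.binary_dilation(
        out[:, :, slice_index], structure=structure, iterations=int(extra_voxels)
    )
    if out.sum() == data.sum():
        raise DefectError("slice_oblong dilation changed nothing")
    return out, {"slice_index": int(slice_index), "axis": axis,
                 "extra_voxels": int(extra_voxels)}


_INJECTORS = {
    "missing_slices": _inject_missing_slices,
    "detached_island": _inject_detached_island,
    "frame_shift": _inject_frame_shift,
    "interior_void": _inject_interior_void,
    "slice_oblong": _inject_slice_oblong,
}


def inject_defect(mask: StructureMask, defect: DefectSpec) -> tuple[StructureMask, str]:
    """Apply one defect; returns the defective mask and its ground-truth label."""
    if defect.kind == "flat_low_volume":
        raise DefectError(
            "flat_low_volume is a cohort-level defect (an empty-bladder phantom is "
            "generated in place of a full one); use generate_cohort"
        )
    rng = np.random.default_rng(defect.rng_seed)
    data, _ = _INJECTORS[defect.kind](mask.data, rng, **defect.params)
    if np.array_equal(data, mask.data):
        raise DefectError(f"defect {defect.kind} did not change the mask")
    return StructureMask(mask.grid, data, roi_name=mask.roi_name), f"defect:{defect.kind}"


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _kind_counts(mix: dict[str, float], n_def: int) -> list[str]:
    """Deterministic largest-remainder apportionment of defect kinds."""
    kinds = sorted(mix)
    weights = np.array([mix[k] for k in kinds], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise MaskValidationError("defect_mix weights must be non-negative with positive sum")
    quota = weights / weights.sum() * n_def
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder, kind="stable")[: n_def - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for k, c in zip(kinds, counts):
        out.extend([k] * int(c))
    return out


def _bladder_clean_params(scales: np.ndarray, clean_rows: np.ndarray) -> dict[int, dict]:
    """Rank-based shape assignment for clean full bladders.

    The largest 60% by scale are elongated (axis cycled LR/AP/IS, elongation
    0.10-0.25 increasing with rank); the small ones stay spherical.  This
    couples shape-extremity to volume so that the cohort's ratio-percentile
    tails are occupied by large bladders only, whatever the seed — small
    *clean* bladders then never trip the low-volume AND extreme-ratio rule.
    """
    order = clean_rows[np.argsort(scales[clean_rows], kind="stable")]
    m = order.size
    n_elong = int(round(0.6 * m))
    start = m - n_elong
    params: dict[int, dict] = {}
    for rank, row in enumerate(order):
        if rank < start or n_elong == 0:
            params[row] = {"scale": float(scales[row])}
        else:
            frac = (rank - start) / max(1, n_elong - 1)
            params[row] = {
                "scale": float(scales[row]),
                "elong_axis": ("lr", "ap", "is")[(rank - start) % 3],
                "elong": 0.10 + 0.15 * frac,
            }
    return params


def generate_cohort(
    organ: str,
    n: int,
    defect_fraction: float,
    seed: int,
    out_dir: str | Path,
    defect_mix: dict[str, float] | None = None,
    fmt: str = "rle_json",
    grid: VoxelGrid | None = None,
) -> CohortManifest:
    """Write a labeled cohort of phantom masks plus its manifest CSV.

    Deterministic: identical arguments give byte-identical files.  The number
    of defect rows is ``round(n * defect_fraction)``; defect kinds follow
    ``defect_mix`` (defaults per organ), assigned by largest remainder.
    """
    if organ not in COHORT_ORGANS:
        raise MaskValidationError(f"unknown cohort organ {organ!r}; choose from {COHORT_ORGANS}")
    if n < 10:
        raise MaskValidationError(f"cohort size must be >= 10, got {n}")
    if not (0.0 <= defect_fraction <= 1.0):
        raise MaskValidationError("defect_fraction must be in [0, 1]")
    mix = defect_mix if defect_mix is not None else _DEFAULT_MIX.get(
        organ, {"missing_slices": 1.0}
    )
    for kind in mix:
        if kind not in DEFECT_KINDS:
            raise MaskValidationError(f"unknown defect kind {kind!r} in defect_mix")
        if kind == "flat_low_volume" and organ != "bladder":
            raise MaskValidationError("flat_low_volume defects apply to bladder cohorts only")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"rle_json": ".rle.json", "nifti": ".nii"}[fmt]

    rng = np.random.default_rng(seed)
    n_def = int(round(n * defect_fraction))
    defect_rows = np.sort(rng.choice(n, size=n_def, replace=False)) if n_def else np.array([], int)
    kinds = _kind_counts(mix, n_def)
    kind_by_row = dict(zip(defect_rows.tolist(), kinds))
    row_seeds = rng.integers(0, 2**31 - 1, size=n)
    defect_seeds = rng.integers(0, 2**31 - 1, size=n)
    scales = rng.uniform(0.85, 1.15, size=n)  # consumed by bladder cohorts only

    clean_organ = "bladder_full" if organ == "bladder" else organ
    grid = grid or default_grid(clean_organ)

    bladder_params: dict[int, dict] = {}
    if organ == "bladder":
        clean_rows = np.array([i for i in range(n) if kind_by_row.get(i) != "flat_low_volume"])
        bladder_params = _bladder_clean_params(scales, clean_rows)

    records = []
    for i in range(n):
        kind = kind_by_row.get(i)
        if organ == "bladder" and kind == "flat_low_volume":
            mask = generate_phantom(PhantomSpec("bladder_empty", grid,
                                                rng_seed=int(row_seeds[i])))
            label = "defect:flat_low_volume"
        else:
            params = bladder_params.get(i, {}) if organ == "bladder" else {}
            mask = generate_phantom(
                PhantomSpec(clean_organ, grid, params=params, rng_seed=int(row_seeds[i]))
            )
            if kind is None:
                label = "clean"
            else:
                mask, label = inject_defect(mask, DefectSpec(kind, rng_seed=int(defect_seeds[i])))
        fname = f"{organ}_{i:03d}{ext}"
        write_mask(mask, out_dir / fname, format=fmt)
        records.append(
            {
                "patient_id": f"P{i:03d}",
                "roi_name": ORGAN_ROI[organ],
                "mask_path": fname,
                "ground_truth_label": label,
            }
        )

    manifest_path = out_dir / "manifest.csv"
    header = [
        "contourqa synthetic cohort v1",
        f"prng=numpy-PCG64 seed={seed} organ={organ} n={n} "
        f"defect_fraction={defect_fraction}",
        f"defect_mix={json.dumps(mix, sort_keys=True)}",
        f"jitter_ranges={json.dumps(JITTER_RANGES[clean_organ], sort_keys=True)}",
    ]
    write_manifest(pd.DataFrame(records), manifest_path, header_lines=header)
    return read_manifest(manifest_path)
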