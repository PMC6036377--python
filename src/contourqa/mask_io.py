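"""Read/write structure masks (NIfTI, RLE-JSON) and cohort manifests (CSV).

The RLE-JSON dialect is repo-defined::

    {"dims": [X, Y, Z], "spacing_mm": [sx, sy, sz], "transitions": [t0, t1, ...]}

with 0-based transitions into the x-fastest linearization, strictly
increasing, interpreted as half-open runs [t0, t1), [t2, t3), ...  An odd
transition count is a validation error.  An optional "roi_name" key is
preserved.

NIfTI volumes are canonicalized on load so the in-memory array axes are always
(x=LR, y=AP, z=IS) regardless of on-disk axis order; orientation metadata
beyond the axis permutation (flips, obliquity) is ignored — the integrity
checks only need a consistent grid, not patient-space pose.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ManifestSchemaError, MaskFormatError, MaskValidationError
from .mask_core import RleMask, StructureMask, VoxelGrid, rle_decode, rle_encode

__all__ = [
    "read_mask",
    "write_mask",
    "CohortManifest",
    "read_manifest",
    "write_manifest",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ("patient_id", "roi_name", "mask_path")
_LABEL_RE = re.compile(r"^(clean|defect:[A-Za-z0-9_]+)$")


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".rle.json") or name.endswith(".json"):
        return "rle_json"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise MaskFormatError(f"cannot infer mask format from file name {path.name!r}")


def read_mask(path: str | Path, format: str = "auto") -> StructureMask:
    """Load a structure mask from NIfTI or RLE-JSON.

    The returned mask uses the canonical (x, y, z) axis order whatever the
    on-disk layout was.
    """
    path = Path(path)
    if not path.exists():
        raise MaskFormatError(f"mask file not found: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "rle_json":
        return _read_rle_json(path)
    raise MaskFormatError(f"unknown mask format {fmt!r}")


def write_mask(mask: StructureMask, path: str | Path, format: str = "auto") -> None:
    """Write a mask; ``read_mask(write_mask(m))`` reproduces m exactly."""
    path = Path(path)
    if not path.parent.is_dir():
        raise MaskFormatError(f"parent directory does not exist: {path.parent}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt == "nifti":
        _write_nifti(mask, path)
    elif fmt == "rle_json":
        _write_rle_json(mask, path)
    else:
        raise MaskFormatError(f"unknown mask format {fmt!r}")


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> StructureMask:
    try:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
    except MaskFormatError:
        raise
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise MaskFormatError(f"could not read NIfTI file {path}: {exc}") from exc
    if arr.ndim != 3:
        raise MaskValidationError(
            f"{path.name}: expected a 3D volume, got {arr.ndim} dimensions"
        )
    finite = np.isfinite(arr)
    if not finite.all():
        raise MaskValidationError(f"{path.name}: volume contains non-finite values")
    near0 = np.abs(arr) <= 1e-6
    near1 = np.abs(arr - 1) <= 1e-6
    if not np.all(near0 | near1):
        bad = arr[~(near0 | near1)]
        raise MaskValidationError(
            f"{path.name}: volume is not binary (e.g. value {bad.flat[0]!r})"
        )
    data = arr > 0.5

    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    perm = _axis_permutation(img.affine)
    data = np.transpose(data, perm)
    zooms = zooms[list(perm)]
    grid = VoxelGrid(*data.shape, *zooms)
    return StructureMask(grid, data)


def _axis_permutation(affine: np.ndarray | None) -> tuple[int, int, int]:
    """Map on-disk data axes to canonical (x, y, z); flips are ignored.

    ``ornt[i, 0]`` is the world axis that data axis i is closest to; the
    permutation placing data axes in world order is its argsort.
    """
    if affine is None:
        return (0, 1, 2)
    try:
        ornt = nib.orientations.io_orientation(np.asarray(affine, dtype=float))
    except Exception:
        return (0, 1, 2)
    if np.any(~np.isfinite(ornt[:, 0])):
        return (0, 1, 2)
    return tuple(int(i) for i in np.argsort(ornt[:, 0]))


def _write_nifti(mask: StructureMask, path: Path) -> None:
    g = mask.grid
    affine = np.diag([g.x_spacing, g.y_spacing, g.z_spacing, 1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms((g.x_spacing, g.y_spacing, g.z_spacing))
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise MaskFormatError(f"could not write NIfTI file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# RLE-JSON
# ---------------------------------------------------------------------------

def _read_rle_json(path: Path) -> StructureMask:
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise MaskFormatError(f"could not read RLE-JSON file {path}: {exc}") from exc
    for key in ("dims", "spacing_mm", "transitions"):
        if key not in obj:
            raise MaskFormatError(f"{path.name}: RLE-JSON missing required key {key!r}")
    dims = obj["dims"]
    spacing = obj["spacing_mm"]
    if len(dims) != 3 or len(spacing) != 3:
        raise MaskValidationError(f"{path.name}: dims and spacing_mm must have length 3")
    grid = VoxelGrid(*dims, *spacing)
    rle = RleMask(grid, np.asarray(obj["transitions"], dtype=np.int64))
    return StructureMask(grid, rle_decode(rle), roi_name=obj.get("roi_name"))


def _write_rle_json(mask: StructureMask, path: Path) -> None:
    g = mask.grid
    obj = {
        "dims": [g.x_dim, g.y_dim, g.z_dim],
        "spacing_mm": [g.x_spacing, g.y_spacing, g.z_spacing],
        "transitions": rle_encode(mask).transitions.tolist(),
    }
    if mask.roi_name is not None:
        obj["roi_name"] = mask.roi_name
    try:
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True, separators=(",", ":"))
            fh.write("\n")
    except OSError as exc:
        raise MaskFormatError(f"could not write RLE-JSON file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Rows of (patient_id, roi_name, mask_path [, ground_truth_label]).

    ``table.mask_path`` holds absolute, resolved paths.  Rows whose mask file
    did not exist at load time are reported in ``errors`` (and dropped from
    ``table``) rather than raising — a QA tool must not die on the data it
    polices.
    """

    table: pd.DataFrame
    errors: list[dict] = field(default_factory=list)
    path: Path | None = None

    def __len__(self) -> int:
        return len(self.table)


def read_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Relative mask paths are resolved against the manifest's directory.  Lines
    starting with ``#`` are treated as comments (cohort generators record
    their provenance there).
    """
    path = Path(path)
    if not path.exists():
        raise ManifestSchemaError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path, comment="#", dtype=str)
    except Exception as exc:
        raise ManifestSchemaError(f"could not parse manifest CSV {path}: {exc}") from exc

    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(
            f"manifest {path.name} missing required column(s): {', '.join(missing)}"
        )
    if "ground_truth_label" not in df.columns:
        df["ground_truth_label"] = pd.NA

    dup = df.duplicated(subset=["patient_id", "roi_name"])
    if dup.any():
        pairs = df.loc[dup, ["patient_id", "roi_name"]].itertuples(index=False)
        raise ManifestSchemaError(
            "duplicate (patient_id, roi_name) pairs: "
            + "; ".join(f"({p}, {r})" for p, r in pairs)
        )

    labels = df["ground_truth_label"]
    bad = labels.notna() & ~labels.fillna("").str.match(_LABEL_RE)
    if bad.any():
        raise ManifestSchemaError(
            f"invalid ground_truth_label value(s): {sorted(labels[bad].unique())}; "
            "expected 'clean' or 'defect:<kind>'"
        )

    errors: list[dict] = []
    resolved = []
    keep = np.ones(len(df), dtype=bool)
    for i, p in enumerate(df["mask_path"]):
        mp = Path(p)
        if not mp.is_absolute():
            mp = path.parent / mp
        if not mp.exists():
            errors.append(
                {
                    "patient_id": df["patient_id"].iloc[i],
                    "roi_name": df["roi_name"].iloc[i],
                    "mask_path": str(mp),
                    "error": "mask file not found",
                }
            )
            keep[i] = False
            resolved.append(str(mp))
        else:
            resolved.append(str(mp.resolve()))
    df = df.assign(mask_path=resolved)
    return CohortManifest(table=df[keep].reset_index(drop=True), errors=errors, path=path)


def write_manifest(
    table: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None
) -> None:
    """Write a manifest CSV with optional ``#`` provenance comment lines."""
    path = Path(path)
    cols = [c for c in ("patient_id", "roi_name", "mask_path", "ground_truth_label")
            if c in table.columns]
    with open(path, "w", newline="\n") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, columns=cols, index=False, lineterminator="\n")
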