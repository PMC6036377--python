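# contourqa

Data-integrity checks for organ contours in radiotherapy treatment planning.

When organs at risk (bladder, femoral heads, rectum, spinal cord, brainstem,
prostate) are contoured on planning CT — manually or by auto-segmentation —
errors creep in: missing slices, in-plane frame shifts, stray voxel islands,
empty-bladder scans in a full-bladder protocol, femoral "head" contours that
silently include the shaft.  Treated as-is, such contours misreport dose to
critical anatomy and poison downstream predictive models.  `contourqa` screens
cohorts of binary structure masks for these problems, for physicists and data
scientists curating clinical radiotherapy databases.

## What it computes

A structure mask lives on a voxel grid with anisotropic spacing
(x = left–right, y = anterior–posterior, z = inferior–superior).  Masks are
stored run-length encoded: the 0-based linear indices (x fastest:
`i = z·X·Y + y·X + x`) where the binary sequence changes, read as half-open
runs.  Voxel coordinates are reconstructed as

```
z = ⌊i / (X·Y)⌋,   y = ⌊(i − z·X·Y) / X⌋,   x = i − z·X·Y − y·X.
```

From the reconstructed indices come the geometric features — volume
(voxel count × voxel volume), per-axis *extent* (max − min coordinate, in
voxels and mm), per-slice LR/AP extents and their range across slices, and
the three extent ratios LR/AP, LR/IS, AP/IS.

**Per-contour contiguity checks.**

* *Extent check*: each axis's occupied coordinate set must fill the whole
  range `[min, max]` (distinct count = extent + 1).  Fast, but blind to
  defects that leave every axis projection complete.
* *Region growing over volume*: iterative closure from a seed voxel, adding
  all set voxels within Euclidean radius √3 (voxel-index units) of the
  visited set — exactly the 26-connectivity component of the seed.  The mask
  is contiguous iff the closure visits every voxel.  Neighbor lookup uses a
  k-d tree fixed-radius ball query.

**Cohort percentile models** (thresholds recomputed per cohort, linear
interpolation between closest ranks):

* *Bladder emptiness*: volume below the cohort 25th percentile AND any extent
  ratio outside the cohort [P10, P90].
* *Femoral ball/shaft*: volume above the 20th percentile AND IS extent > 60 mm
  AND LR/AP < 1.5 ⇒ ball+shaft, else ball-only.
* *Slice-based extent*: LR and AP per-slice-extent range-of-ranges both above
  their cohort 90th percentiles (configurable to OR).

A seeded synthetic phantom generator provides labeled cohorts (organ-shaped
masks with planted `missing_slices`, `detached_island`, `frame_shift`,
`interior_void`, `slice_oblong`, `flat_low_volume` defects) to validate every
detector against known ground truth.

## Worked example

The classic failure of projection-based checking, in four voxels:

```python
import contourqa as cq

m = cq.StructureMask.from_voxels(cq.VoxelGrid(4, 4, 4),
                                 [(0, 0, 0), (1, 1, 1), (2, 3, 2), (3, 2, 3)])
print("extent check:", cq.check_extent_contiguity(m).contiguous)
v = cq.check_region_growing_contiguity(m)
print("region growing:", v.contiguous, v.detail)
```

prints

```
extent check: True
region growing: False {'visited_count': 2, 'total_count': 4, 'seed_linear_index': 0}
```

Every axis projection of this mask is gap-free, so the extent check passes —
yet region growing visits only 2 of 4 voxels: the structure is two separate
pieces ({(0,0,0),(1,1,1)} and {(2,3,2),(3,2,3)}, nearest inter-piece distance
√6 > √3).

End to end, from the shell — simulate a spinal-cord cohort with 10% planted
frame shifts and screen it:

```sh
contour-qa simulate --organ spinal_cord --n 50 --defect-fraction 0.1 \
    --seed 7 --out-dir demo
contour-qa check --manifest demo/manifest.csv \
    --checks extent,region_growing,slice_extent --out report.json
```

The report's summary shows exactly the five planted rows flagged, and (because
the manifest carries ground-truth labels) a per-detector confusion block:

```json
"flag_counts": {"slice_extent_outlier": 5}
"slice_extent": {"sensitivity": 1.0, "precision": 1.0}
```

The frame-shifted cords stay fully connected (both contiguity checks pass);
only the slice-extent model can see them — while, conversely, a cord with a
deleted interior slice trips both contiguity checks and leaves the slice-extent
features untouched.

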