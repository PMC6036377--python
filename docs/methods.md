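# Methods

This note documents the models, conventions, numerical choices and known
limitations of `contourqa`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Grid and mask conventions

A structure mask is a 3D binary array on a `VoxelGrid` with axis semantics
x = left–right (LR), y = anterior–posterior (AP), z = inferior–superior (IS),
and positive per-axis spacing in mm.  The linear index of voxel (x, y, z) is
`z·(X·Y) + y·X + x` — x varies fastest; this is the unique ordering consistent
with the index-reconstruction equations

```
z = ⌊i/(X·Y)⌋,  y = ⌊(i − z·X·Y)/X⌋,  x = i − z·X·Y − y·X,
```

which `VoxelGrid.delinearize` implements verbatim and `linearize` inverts.
Coordinates are 0-based.

**RLE dialect.**  Run-length encoding stores the strictly increasing 0-based
linear indices where the mask changes value; pairs are half-open runs
`[t0, t1), [t2, t3), …`.  A run touching the final voxel closes at `X·Y·Z`
(so that value, and only that value, may equal the total voxel count).  An
odd transition count is invalid.  Half-open pairs make run filling
unambiguous and the decode a strict inverse of encode; both directions are
exercised as an identity property on random masks.

**Extent.**  Reported both as `range_voxels = max − min` (the raw coordinate
subtraction) and `span_voxels = range + 1`, plus `range_mm = range × spacing`.
The distinction matters twice: the extent-contiguity rule must compare the
distinct-coordinate count against the *span* (the only reading under which a
solid block is contiguous), and the cohort models use *mm* ranges because
clinical grids are anisotropic — voxel-count ratios would depend on slice
thickness.  Whether extents are best consumed in voxels or mm is
situation-dependent, so both are exposed.

**In-slice extents** are LR/AP only; a z-slice has no IS spread.  The
slice-extent feature is the range across occupied slices of the per-slice
extent ("range of ranges"), per direction, 0 for a single occupied slice.

**Extent ratios** (LR/AP, LR/IS, AP/IS) are computed from mm ranges and are
undefined (NaN + flag, not an exception) when any axis range is 0, so that
degenerate contours (single voxel, single slice) surface as automatic
outliers in the cohort layer rather than crashing a batch run.

## File formats

NIfTI masks are accepted when 3D and binary (values within 1e-6 of {0, 1},
then thresholded at 0.5).  On load the data axes are permuted to the
canonical (x, y, z) order using the affine's closest world axes; orientation
beyond the permutation (flips, obliquity) is deliberately ignored — the
integrity checks need a consistent grid, not patient-space pose.  The
RLE-JSON dialect (`dims`, `spacing_mm`, `transitions`, optional `roi_name`)
is the package's own text format and round-trips masks exactly (spacing to
1e-6 mm).  Cohort manifests are CSV
(`patient_id, roi_name, mask_path, ground_truth_label`) with `#` comment
lines for provenance; duplicate (patient, ROI) keys and malformed labels are
schema errors, while unresolvable mask paths become explicit error rows.

## Contiguity checks

**Extent check.**  For each axis, collect the distinct occupied coordinate
values; the mask is contiguous iff every axis's set equals the full integer
range [min, max].  Missing values inside the range are reported as
`gap_positions`.  This is the whole-axis (projection) reading; a per-slice 2D
variant would be stricter but is intentionally not what this check does —
the slice-level signal belongs to the slice-extent model.

**Region growing.**  From the seed (the set voxel with the lowest linear
index — deterministic, and the verdict is provably seed-invariant since the
closure is the seed's connectivity component, which tests confirm
exhaustively on small masks), repeatedly add every unvisited set voxel within
Euclidean distance `neighbor_radius` of the visited set, until a fixed point.
The frontier is an explicit queue, never call-stack recursion: clinical masks
reach 10^5–10^6 voxels and recursion depth would be unbounded.  Neighbor
lookup uses `scipy.spatial.cKDTree.query_ball_point`; the contract is that
results equal exhaustive Euclidean comparison at 1e-9 tolerance on the
radius, so the tree is a pure optimization.  Voxel coordinates are integers,
squared distances are integers, and the default radius² = 3, so the 1e-9
additive slack cannot change any verdict.

Radius bands map to digital connectivities: [1, √2) → 6, [√2, √3) → 18,
[√3, 2) → 26.  The default √3 gives 26-connectivity on the unit-index grid.

**Ordering of the two checks.**  A fully missing coordinate plane separates
26-neighborhoods, so every extent-detected discontiguity is also a
region-growing discontiguity; the converse fails (four voxels whose axis
projections are all complete but which form two components), which is why the
region-growing check is strictly stronger.  Both facts are asserted in the
test suite and recomputed by the acceptance script.

**Empty masks** get a distinct verdict (`contiguous=None, empty=True`) from
both checks instead of an exception: an empty clinical contour is neither
contiguous nor noncontiguous but always reportable, and the cohort runner
raises an `empty_mask` flag for it.  The lower-level primitives
(`region_grow`, `compute_extent`, `slice_extents`) do raise on empty input.

**Oracle.**  `connected_components_oracle` labels components by BFS over the
"within radius" relation evaluated by direct pairwise distances, chunked for
memory, with no spatial index — an implementation deliberately disjoint from
`region_grow` so the two can check each other.  Tests add two further
independent routes (union-find over the 26-neighbor graph;
`skimage.measure.label` / `scipy.ndimage.label`) on random masks.

## Cohort models

All three models recompute their percentile thresholds on the analyzed cohort
(fit == analyze), matching a development/experimental-group workflow; because
they are scikit-learn estimators, fitting on one cohort and predicting
another gives a frozen-threshold variant for free.  The percentile method is
pinned to linear interpolation between closest ranks (`numpy` "linear";
p=0 → min, p=100 → max) and recorded in every report, since different
conventions move thresholds by up to one rank.  Each model refuses cohorts
smaller than 8 rows (configurable): below that, percentile thresholds are
noise.  Flags are a pure function of (features, config): row order is
irrelevant, and rescaling all spacings by a constant rescales features but
leaves every flag unchanged (ratios are scale-free; volume/extent percentiles
shift with their cohort).

* **Bladder**: flag iff volume < cohort P25 AND (any ratio < P10 or > P90,
  undefined ratios auto-flagging).  The volume gate and the ratio clause are
  combined with AND — the volume condition is the "initial condition", but
  ratio percentiles are computed over the *full* cohort, not the gated
  subset (gating the percentile population would make the thresholds
  unstable in exactly the low-volume tail the model inspects).
* **Femoral head**: ball+shaft iff volume > cohort P20 AND IS extent >
  `is_range_mm_threshold` AND LR/AP < `lr_over_ap_ratio_threshold`.  The two
  fixed thresholds have no cohort-derived value; the defaults (60 mm, 1.5)
  were chosen once from the synthetic phantom geometry — ball-only IS extent
  ≤ ~34 mm vs ball+shaft ≥ ~104 mm, both shapes near-symmetric in-plane —
  and live in `default_config.yaml`.  A single-pass rule is used; with fixed
  thresholds, iterating it would change nothing.
* **Slice extent**: flag iff LR range-of-ranges > cohort P90 AND AP
  range-of-ranges > its P90.  AND vs OR is genuinely ambiguous as a matter
  of intent (AND is specific to diagonal frame shifts; OR also catches
  single-direction bulges at the cost of more false positives), so it is a
  config switch, defaulting to AND.

## Synthetic phantoms

The generator's job is to provide *labeled* cohorts whose planted defects are
unambiguously detectable (or undetectable) by specific detectors, so that
sensitivity/precision have exact expected values.  Defaults: grids 64×64×80
voxels at 1×1×2 mm (bladder, rectum, femoral, prostate) and 32×32×120 for
cords/brainstem — clinically plausible anisotropy at desk scale, small enough
that a full 150-mask validation run takes seconds.  All randomness flows from
one integer seed through numpy's PCG64 (recorded in the manifest header with
the jitter ranges); cohorts are byte-identical across runs.

Organ shapes: full bladder ≈ 20 mm-radius sphere (scale jitter 0.85–1.15);
empty bladder ≈ flattened 18×12×4 mm ellipsoid; femoral ball = 13–16 mm
sphere; ball+shaft adds an abutting IS cylinder of radius r/2 and length 6r;
spinal cord = 4.5–5.5 mm tube with smooth sinusoidal drift (≤ ~0.3 voxel per
slice — well inside the overlap needed for 26-connectivity between adjacent
disks); rectum = curved 7–9 mm tube; prostate = 20×17×15 mm ellipsoid;
brainstem-like = tapering tube.  Every clean phantom is verified non-empty,
boundary-clear and 26-connected.

**Bladder cohort shape coupling.**  With full-cohort ratio percentiles, some
clean contours necessarily sit beyond P10/P90 of each ratio.  If shape and
volume jittered independently, a small *clean* bladder would occasionally
land in a ratio tail and the bladder model's false-positive count would be
seed-dependent.  The generator therefore couples the two deterministically by
rank: the largest 60% of clean bladders by scale receive an elongation
(0.10–0.25, axis cycling LR/AP/IS with rank), the smaller 40% stay spherical.
The ratio tails are then always occupied by above-median-volume contours, and
the low-volume ∧ extreme-ratio conjunction is satisfied by planted flat
phantoms only — for any seed.  This is a property of the validation cohort,
not of the model.

**Defects.**

* `missing_slices`: interior IS slice(s) deleted.  Removing a full slice
  separates 26-neighborhoods (|Δz| ≥ 2), so both contiguity checks must fire.
* `detached_island`: a small cube placed inside the body's bounding box
  (found via a Euclidean distance transform) strictly farther than √3 from
  every body voxel.  Because the box interior's coordinate shadows are
  already occupied, all axis ranges stay complete: only region growing can
  see it.  `placement="outside"` instead puts the island past the box with an
  empty gap, which the extent check also catches.
* `frame_shift`: one slice's contour additionally appears translated
  in-plane (union of the slice with its shifted copy) — a displaced contour
  landing on a slice that already has content.  A pure translation would
  leave per-slice extents unchanged and be invisible to every feature here;
  the union inflates that slice's LR and AP extents by the shift (default
  (5, 5) voxels, below the tube diameter so the copy overlaps the original
  and contiguity is preserved).
* `interior_void`: a small ball carved at the deepest interior point;
  contiguity and extents unchanged, volume reduced — a deliberate
  nothing-should-fire control.
* `slice_oblong`: one slice dilated along one in-plane axis; visible to the
  slice-extent model only under the OR combination.
* `flat_low_volume` (bladder cohorts only): an empty-bladder phantom
  substituted for a full one — a cohort-level defect rather than a voxel
  edit, since "the wrong organ state was scanned" has no local signature.

## Validation scale and determinism

The acceptance script and test suite run the oracle comparison on 500 random
masks (grids ≤ 12³, densities 0.05–0.6 — sizes where the O(n²) pairwise
oracle is exact and fast), the codec identity on 500 masks, seed-invariance
exhaustively over all seeds of 50 small masks, and the planted-defect
recovery on three cohorts of 50 (10% defects: rectum with missing slices and
detached islands; cords with frame shifts; bladders with flat substitutes).
Expected outcomes are exact: sensitivities and precisions of 1.0 for each
detector on its defect class, extent sensitivity 0 on axis-complete islands,
and byte-identical JSON reports for identical seeds (reports carry no
timestamp unless requested).

## Limitations

The phantoms are smooth solids with uniform "contrast": they do not model
ragged manual contours, multi-lobed organs, holes from pinched polygons, CT
couch removal artifacts, or inter-observer variability, so passing the
planted-defect tests bounds detector behavior only for defects of the planted
geometry and magnitude.  The cohort models' exact-recovery results are
properties of these calibrated cohorts; on clinical data the same models
trade sensitivity against false positives through their percentile and
threshold settings.  DICOM RT-STRUCT polygons are out of scope (masks must
already be rasterized), as are patient-space orientation handling, surface
meshing and runtime benchmarking.
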