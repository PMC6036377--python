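"""Percentile models: pinned percentile method, gating logic, planted outliers."""

import numpy as np
import pandas as pd
import pytest

from contourqa import (
    CohortSizeError,
    MaskValidationError,
    ModelConfig,
    bladder_model,
    build_cohort_table,
    femoral_head_model,
    generate_phantom,
    load_default_config,
    percentile,
    slice_extent_model,
)
from contourqa.cohort_models import (
    BladderEmptinessDetector,
    FemoralHeadShaftClassifier,
    SliceExtentOutlierDetector,
)
from contourqa.synthetic_phantoms import PhantomSpec


class TestPercentile:
    def test_median_of_three(self):
        assert percentile([1, 2, 3], 50) == 2

    def test_linear_interpolation_between_closest_ranks(self):
        assert percentile([0, 10], 25) == 2.5

    def test_endpoints_are_min_and_max(self, rng):
        vals = rng.normal(size=17)
        assert percentile(vals, 0) == vals.min()
        assert percentile(vals, 100) == vals.max()

    def test_permutation_invariant(self, rng):
        vals = list(rng.normal(size=9))
        shuffled = list(vals)
        rng.shuffle(shuffled)
        assert percentile(vals, 37.5) == percentile(shuffled, 37.5)

    def test_empty_list_rejected(self):
        with pytest.raises(MaskValidationError):
            percentile([], 50)


def _phantom_cohort(specs):
    return build_cohort_table(
        (f"P{i:03d}", mask.roi_name, mask)
        for i, mask in enumerate(generate_phantom(s) for s in specs)
    )


def _bladder_cohort(n_full=49, seeds=None, elongate=True):
    """Full bladders with rank-coupled elongation, mimicking generate_cohort."""
    rng = np.random.default_rng(99)
    scales = rng.uniform(0.85, 1.15, size=n_full)
    order = np.argsort(scales)
    specs = [None] * n_full
    n_elong = int(round(0.6 * n_full)) if elongate else 0
    start = n_full - n_elong
    for rank, i in enumerate(order):
        params = {"scale": float(scales[i])}
        if rank >= start and n_elong:
            frac = (rank - start) / max(1, n_elong - 1)
            params.update(elong_axis=("lr", "ap", "is")[(rank - start) % 3],
                          elong=0.10 + 0.15 * frac)
        specs[i] = PhantomSpec("bladder_full", params=params, rng_seed=1000 + i)
    return specs


class TestBladderModel:
    def test_identical_spheres_yield_zero_flags(self):
        specs = [PhantomSpec("bladder_full", params={"scale": 1.0}, rng_seed=5)] * 12
        cohort = _phantom_cohort(specs)
        cohort["patient_id"] = [f"P{i}" for i in range(12)]
        report = bladder_model(cohort)
        assert report.flagged.sum() == 0

    def test_planted_flat_low_volume_phantom_is_the_only_flag(self):
        specs = _bladder_cohort(49) + [PhantomSpec("bladder_empty", rng_seed=7)]
        cohort = _phantom_cohort(specs)
        report = bladder_model(cohort)
        assert report.table.loc[report.flagged, "patient_id"].tolist() == ["P049"]

    def test_low_volume_but_shape_typical_is_not_flagged(self):
        # small sphere: passes the volume gate but has mid-range ratios
        specs = _bladder_cohort(49) + [
            PhantomSpec("bladder_full", params={"scale": 0.70}, rng_seed=11)
        ]
        cohort = _phantom_cohort(specs)
        report = bladder_model(cohort)
        frame = report.table
        assert bool(frame.loc[49, "low_volume"])
        assert not bool(frame.loc[49, "flagged"])

    def test_undefined_ratios_autoflag_when_volume_is_low(self):
        cohort = _phantom_cohort(_bladder_cohort(12))
        row = cohort.iloc[0].copy()
        row[["lr_over_ap", "lr_over_is", "ap_over_is"]] = np.nan
        row["ratios_defined"] = False
        row["volume_mm3"] = 1.0
        row["patient_id"] = "PX"
        cohort = pd.concat([cohort, row.to_frame().T], ignore_index=True)
        report = bladder_model(cohort)
        assert "PX" in report.table.loc[report.flagged, "patient_id"].tolist()

    def test_cohort_floor_enforced(self):
        cohort = _phantom_cohort(_bladder_cohort(5, elongate=False))
        with pytest.raises(CohortSizeError, match="8"):
            bladder_model(cohort)

    def test_flags_invariant_under_row_shuffle(self, rng):
        cohort = _phantom_cohort(_bladder_cohort(20))
        report = bladder_model(cohort)
        shuffled = cohort.sample(frac=1.0, random_state=3).reset_index(drop=True)
        report2 = bladder_model(shuffled)
        assert set(report.table.loc[report.flagged, "patient_id"]) == set(
            report2.table.loc[report2.flagged, "patient_id"]
        )

    def test_flags_invariant_under_global_spacing_rescale(self):
        cohort = _phantom_cohort(_bladder_cohort(16))
        scaled = cohort.copy()
        c = 2.5
        scaled["volume_mm3"] *= c**3
        for col in ("lr_range_mm", "ap_range_mm", "is_range_mm",
                    "lr_slice_range_of_ranges_mm", "ap_slice_range_of_ranges_mm"):
            scaled[col] *= c
        r1, r2 = bladder_model(cohort), bladder_model(scaled)
        assert r1.flagged.tolist() == r2.flagged.tolist()


class TestFemoralHeadModel:
    def _mixed_cohort(self, n_ball=30, n_shaft=20):
        specs = [PhantomSpec("femoral_ball", rng_seed=200 + i) for i in range(n_ball)]
        specs += [PhantomSpec("femoral_ball_shaft", rng_seed=600 + i)
                  for i in range(n_shaft)]
        return _phantom_cohort(specs), n_ball

    def test_sphere_only_cohort_all_ball_only(self):
        cohort, _ = self._mixed_cohort(n_ball=12, n_shaft=0)
        report = femoral_head_model(cohort)
        assert (report.table["classification"] == "ball_only").all()

    def test_mixed_cohort_separates_shaft_contours_exactly(self):
        cohort, n_ball = self._mixed_cohort()
        report = femoral_head_model(cohort)
        got_shaft = set(report.table.loc[report.flagged, "patient_id"])
        expected = {f"P{i:03d}" for i in range(n_ball, n_ball + 20)}
        assert got_shaft == expected

    def test_small_composite_fails_volume_gate(self):
        # a ball+shaft contour scaled to the cohort's low-volume tail is
        # classified ball_only despite its long IS extent
        cohort, n_ball = self._mixed_cohort()
        small = generate_phantom(
            PhantomSpec("femoral_ball_shaft",
                        params={"ball_radius_mm": 8.0}, rng_seed=3)
        )
        extra = build_cohort_table([("PSMALL", small.roi_name, small)])
        cohort = pd.concat([cohort, extra], ignore_index=True)
        report = femoral_head_model(cohort)
        row = report.table[report.table["patient_id"] == "PSMALL"].iloc[0]
        assert row["classification"] == "ball_only"

    def test_is_extent_of_composite_triples_ball_extent(self):
        ball = generate_phantom(
            PhantomSpec("femoral_ball", params={"ball_radius_mm": 14.0}, rng_seed=1))
        comp = generate_phantom(
            PhantomSpec("femoral_ball_shaft", params={"ball_radius_mm": 14.0},
                        rng_seed=1))
        t = build_cohort_table([("a", "femoral_head_left", ball),
                                ("b", "femoral_head_left", comp)])
        assert t.loc[1, "is_range_mm"] >= 3 * t.loc[0, "is_range_mm"]


class TestSliceExtentModel:
    def _cord_cohort(self, n=20):
        return _phantom_cohort(
            [PhantomSpec("spinal_cord", rng_seed=300 + i) for i in range(n)]
        )

    def test_constant_radius_cylinders_unflagged(self):
        from contourqa import StructureMask, VoxelGrid

        grid = VoxelGrid(24, 24, 20, 1.0, 1.0, 2.0)
        xs = np.arange(24)
        masks = []
        for r in np.linspace(4.0, 8.0, 12):
            disk = ((xs[:, None] - 11.5) ** 2 + (xs[None, :] - 11.5) ** 2) <= r**2
            masks.append(StructureMask(grid, np.repeat(disk[:, :, None], 20, 2),
                                       roi_name="cyl"))
        cohort = build_cohort_table(
            (f"P{i}", "cyl", m) for i, m in enumerate(masks))
        report = slice_extent_model(cohort)
        assert report.flagged.sum() == 0

    def test_planted_frame_shift_is_the_only_flag(self):
        from contourqa import DefectSpec, inject_defect

        cohort_masks = [
            generate_phantom(PhantomSpec("spinal_cord", rng_seed=400 + i))
            for i in range(49)
        ]
        shifted, label = inject_defect(
            generate_phantom(PhantomSpec("spinal_cord", rng_seed=449)),
            DefectSpec("frame_shift", rng_seed=9),
        )
        assert label == "defect:frame_shift"
        cohort = build_cohort_table(
            [(f"P{i:03d}", "spinal_cord", m) for i, m in enumerate(cohort_masks)]
            + [("P049", "spinal_cord", shifted)]
        )
        report = slice_extent_model(cohort)
        assert report.table.loc[report.flagged, "patient_id"].tolist() == ["P049"]

    def test_lr_only_bulge_needs_or_combination(self):
        from contourqa import DefectSpec, inject_defect

        masks = [generate_phantom(PhantomSpec("spinal_cord", rng_seed=500 + i))
                 for i in range(19)]
        bulged, _ = inject_defect(
            generate_phantom(PhantomSpec("spinal_cord", rng_seed=519)),
            DefectSpec("slice_oblong", params={"axis": "x", "extra_voxels": 6},
                       rng_seed=2),
        )
        cohort = build_cohort_table(
            [(f"P{i:03d}", "spinal_cord", m) for i, m in enumerate(masks)]
            + [("P019", "spinal_cord", bulged)]
        )
        cfg_and = ModelConfig()
        report_and = slice_extent_model(cohort, cfg_and)
        assert "P019" not in report_and.table.loc[report_and.flagged, "patient_id"].tolist()

        cfg_or = ModelConfig()
        cfg_or.slice_extent.combine = "or"
        report_or = slice_extent_model(cohort, cfg_or)
        assert "P019" in report_or.table.loc[report_or.flagged, "patient_id"].tolist()


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        for est in (BladderEmptinessDetector(), FemoralHeadShaftClassifier(),
                    SliceExtentOutlierDetector()):
            params = est.get_params()
            est2 = type(est)(**params)
            assert est2.get_params() == params

    def test_fit_exposes_thresholds_and_predict_signs(self):
        cohort = _phantom_cohort(_bladder_cohort(16))
        est = BladderEmptinessDetector().fit(cohort)
        assert est.volume_threshold_ > 0
        pred = est.predict(cohort)
        assert set(np.unique(pred)) <= {-1, 1}

    def test_frozen_thresholds_apply_to_new_cohort(self):
        train = _phantom_cohort(_bladder_cohort(20))
        est = SliceExtentOutlierDetector().fit(train)
        test = _phantom_cohort(_bladder_cohort(12))
        flags = est.flag_frame(test)
        assert len(flags) == 12  # thresholds from train, applied unchanged

    def test_default_config_matches_shipped_yaml(self):
        cfg = load_default_config()
        assert cfg.femoral_head.is_range_mm_threshold == 60.0
        assert cfg.slice_extent.combine == "and"
        assert cfg.percentile_method == "linear"
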