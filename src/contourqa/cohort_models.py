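"""Cohort-level percentile-threshold outlier models.

Three data-driven models operate on a per-contour feature table (one row per
(patient, ROI)):

* **Bladder emptiness** — flag contours in the bottom volume quartile whose
  extent ratios are extreme (below the 10th / above the 90th cohort
  percentile for any of LR/AP, LR/IS, AP/IS); undefined ratios auto-flag.
  Intended to find empty-bladder scans in a full-bladder protocol.
* **Femoral head ball/shaft distinction** — contours above the 20th volume
  percentile with a long inferior-superior extent and near-symmetric in-plane
  extents are classified as ball+shaft; everything else as ball-only.
* **Slice-based extent outliers** — contours whose per-slice extent
  range-of-ranges exceeds the cohort 90th percentile in LR and (or, per
  config) AP; sensitive to frame shifts and oblong slices that leave the
  whole-ROI extent unremarkable.

All three are scikit-learn estimators: ``fit`` computes the cohort thresholds
(trailing-underscore attributes), ``predict`` applies them.  Thresholds are
recomputed per analyzed cohort by default; fitting on one cohort and
predicting another reproduces a frozen-threshold workflow.

The percentile method is pinned to linear interpolation between closest ranks
(p=0 -> min, p=100 -> max) and recorded in every report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin, OutlierMixin

from .errors import CohortSizeError, MaskValidationError
from .mask_core import (
    StructureMask,
    compute_extent,
    compute_volume,
    extent_ratios,
    slice_extents,
)

__all__ = [
    "PERCENTILE_METHOD",
    "FEATURE_COLUMNS",
    "RATIO_COLUMNS",
    "percentile",
    "compute_features",
    "build_cohort_table",
    "BladderEmptinessDetector",
    "FemoralHeadShaftClassifier",
    "SliceExtentOutlierDetector",
    "ModelConfig",
    "BladderConfig",
    "FemoralHeadConfig",
    "SliceExtentConfig",
    "FlagReport",
    "bladder_model",
    "femoral_head_model",
    "slice_extent_model",
    "load_default_config",
]

PERCENTILE_METHOD = "linear"

RATIO_COLUMNS = ("lr_over_ap", "lr_over_is", "ap_over_is")

FEATURE_COLUMNS = (
    "volume_mm3",
    "lr_range_mm",
    "ap_range_mm",
    "is_range_mm",
    "lr_over_ap",
    "lr_over_is",
    "ap_over_is",
    "ratios_defined",
    "lr_slice_range_of_ranges_mm",
    "ap_slice_range_of_ranges_mm",
    "voxel_count",
    "empty_mask",
)


def percentile(values: Iterable[float], p: float, method: str = PERCENTILE_METHOD) -> float:
    """Percentile with linear interpolation between closest ranks.

    Permutation-invariant; p=0 gives the minimum, p=100 the maximum.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise MaskValidationError("percentile of an empty value list is undefined")
    if not (0.0 <= p <= 100.0):
        raise MaskValidationError(f"percentile p must be in [0, 100], got {p}")
    return float(np.percentile(arr, p, method=method))


def compute_features(mask: StructureMask) -> dict:
    """Feature row for one contour; NaNs (plus ``empty_mask``) for empty masks."""
    if mask.is_empty:
        row = {c: float("nan") for c in FEATURE_COLUMNS}
        row.update(volume_mm3=0.0, voxel_count=0, ratios_defined=False, empty_mask=True)
        return row
    ext = compute_extent(mask)
    rat = extent_ratios(ext)
    prof = slice_extents(mask)
    return {
        "volume_mm3": compute_volume(mask),
        "lr_range_mm": ext.lr_range_mm,
        "ap_range_mm": ext.ap_range_mm,
        "is_range_mm": ext.is_range_mm,
        "lr_over_ap": rat.lr_over_ap,
        "lr_over_is": rat.lr_over_is,
        "ap_over_is": rat.ap_over_is,
        "ratios_defined": rat.defined,
        "lr_slice_range_of_ranges_mm": prof.lr_range_of_ranges_mm,
        "ap_slice_range_of_ranges_mm": prof.ap_range_of_ranges_mm,
        "voxel_count": mask.voxel_count,
        "empty_mask": False,
    }


def build_cohort_table(
    records: Iterable[tuple[str, str, StructureMask]]
) -> pd.DataFrame:
    """Cohort feature table from (patient_id, roi_name, mask) records."""
    rows = []
    for patient_id, roi_name, mask in records:
        row = {"patient_id": patient_id, "roi_name": roi_name}
        row.update(compute_features(mask))
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "roi_name", *FEATURE_COLUMNS])


def _as_frame(X, required: tuple[str, ...]) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise MaskValidationError("cohort models expect a feature DataFrame")
    missing = [c for c in required if c not in X.columns]
    if missing:
        raise MaskValidationError(f"feature table missing column(s): {', '.join(missing)}")
    return X


class _CohortSizeCheck:
    min_cohort_size: int

    def _check_size(self, X: pd.DataFrame) -> None:
        if len(X) < self.min_cohort_size:
            raise CohortSizeError(
                f"{type(self).__name__} needs at least {self.min_cohort_size} cohort "
                f"rows (got {len(X)}); percentile thresholds are meaningless below "
                "this floor"
            )


class BladderEmptinessDetector(BaseEstimator, OutlierMixin, _CohortSizeCheck):
    """Flag low-volume bladders with extreme extent ratios.

    A row is flagged iff its volume is strictly below the cohort
    ``volume_percentile`` (default: bottom quartile) AND any of the three
    extent ratios falls strictly below the cohort ``ratio_low_percentile`` or
    strictly above ``ratio_high_percentile`` — with undefined ratios
    auto-satisfying the ratio clause.  Ratio percentiles are computed over the
    full cohort (the volume gate is the "initial condition", not the ratio
    population).

    Following the scikit-learn outlier convention, :meth:`predict` returns -1
    for flagged rows and +1 otherwise; :meth:`flag_frame` gives per-row
    trigger detail.
    """

    def __init__(
        self,
        volume_percentile: float = 25.0,
        ratio_low_percentile: float = 10.0,
        ratio_high_percentile: float = 90.0,
        min_cohort_size: int = 8,
    ):
        self.volume_percentile = volume_percentile
        self.ratio_low_percentile = ratio_low_percentile
        self.ratio_high_percentile = ratio_high_percentile
        self.min_cohort_size = min_cohort_size

    _required = ("volume_mm3", *RATIO_COLUMNS, "ratios_defined")

    def fit(self, X: pd.DataFrame, y=None) -> "BladderEmptinessDetector":
        X = _as_frame(X, self._required)
        self._check_size(X)
        for p in (self.volume_percentile, self.ratio_low_percentile,
                  self.ratio_high_percentile):
            if not (0.0 < p < 100.0):
                raise MaskValidationError(f"percentile parameters must be in (0, 100), got {p}")
        self.volume_threshold_ = percentile(X["volume_mm3"].to_numpy(), self.volume_percentile)
        self.ratio_thresholds_ = {}
        for col in RATIO_COLUMNS:
            vals = X[col].to_numpy(dtype=float)
            if np.isnan(vals).all():
                self.ratio_thresholds_[col] = (float("nan"), float("nan"))
            else:
                self.ratio_thresholds_[col] = (
                    percentile(vals, self.ratio_low_percentile),
                    percentile(vals, self.ratio_high_percentile),
                )
        self.n_rows_ = len(X)
        return self

    def flag_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _as_frame(X, self._required)
        vol = X["volume_mm3"].to_numpy(dtype=float)
        low_volume = vol < self.volume_threshold_
        undefined = ~X["ratios_defined"].astype(bool).to_numpy()
        ratio_outlier = undefined.copy()
        triggers = {}
        for col in RATIO_COLUMNS:
            lo, hi = self.ratio_thresholds_[col]
            vals = X[col].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                out = (vals < lo) | (vals > hi)
            out &= ~np.isnan(vals)
            triggers[f"{col}_outlier"] = out
            ratio_outlier |= out
        return pd.DataFrame(
            {
                "low_volume": low_volume,
                "ratios_undefined": undefined,
                **triggers,
                "flagged": low_volume & ratio_outlier,
            },
            index=X.index,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.where(self.flag_frame(X)["flagged"].to_numpy(), -1, 1)

    def thresholds(self) -> dict:
        return {
            "volume_mm3_p{:g}".format(self.volume_percentile): self.volume_threshold_,
            **{
                f"{col}_p{self.ratio_low_percentile:g}_p{self.ratio_high_percentile:g}":
                list(self.ratio_thresholds_[col])
                for col in RATIO_COLUMNS
            },
            "percentile_method": PERCENTILE_METHOD,
        }


class FemoralHeadShaftClassifier(BaseEstimator, ClassifierMixin, _CohortSizeCheck):
    """Distinguish femoral head ball-only contours from ball+shaft contours.

    ``ball_shaft`` iff volume is strictly above the cohort ``volume_percentile``
    AND the inferior-superior extent exceeds ``is_range_mm_threshold`` AND the
    LR/AP ratio is below ``lr_over_ap_ratio_threshold`` (a shaft lengthens the
    IS extent while keeping the in-plane footprint symmetric).  The two fixed
    thresholds are configuration values; the defaults were calibrated once on
    the synthetic femoral phantoms and live in ``default_config.yaml``.
    """

    def __init__(
        self,
        volume_percentile: float = 20.0,
        is_range_mm_threshold: float = 60.0,
        lr_over_ap_ratio_threshold: float = 1.5,
        min_cohort_size: int = 8,
    ):
        self.volume_percentile = volume_percentile
        self.is_range_mm_threshold = is_range_mm_threshold
        self.lr_over_ap_ratio_threshold = lr_over_ap_ratio_threshold
        self.min_cohort_size = min_cohort_size

    _required = ("volume_mm3", "is_range_mm", "lr_over_ap")

    def fit(self, X: pd.DataFrame, y=None) -> "FemoralHeadShaftClassifier":
        X = _as_frame(X, self._required)
        self._check_size(X)
        if not (0.0 < self.volume_percentile < 100.0):
            raise MaskValidationError("volume_percentile must be in (0, 100)")
        if self.is_range_mm_threshold <= 0 or self.lr_over_ap_ratio_threshold <= 0:
            raise MaskValidationError("femoral thresholds must be > 0")
        self.volume_threshold_ = percentile(
            X["volume_mm3"].to_numpy(), self.volume_percentile
        )
        self.classes_ = np.array(["ball_only", "ball_shaft"])
        self.n_rows_ = len(X)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = _as_frame(X, self._required)
        vol = X["volume_mm3"].to_numpy(dtype=float)
        is_range = X["is_range_mm"].to_numpy(dtype=float)
        lr_over_ap = X["lr_over_ap"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            shaft = (
                (vol > self.volume_threshold_)
                & (is_range > self.is_range_mm_threshold)
                & (lr_over_ap < self.lr_over_ap_ratio_threshold)
            )
        return np.where(shaft, "ball_shaft", "ball_only")

    def thresholds(self) -> dict:
        return {
            "volume_mm3_p{:g}".format(self.volume_percentile): self.volume_threshold_,
            "is_range_mm_threshold": self.is_range_mm_threshold,
            "lr_over_ap_ratio_threshold": self.lr_over_ap_ratio_threshold,
            "percentile_method": PERCENTILE_METHOD,
        }


class SliceExtentOutlierDetector(BaseEstimator, OutlierMixin, _CohortSizeCheck):
    """Flag contours whose per-slice extent spread is extreme for the cohort.

    A row is flagged iff its LR slice-extent range-of-ranges is strictly above
    the cohort ``percentile`` AND (``combine="and"``, the default) or OR
    (``combine="or"``) the AP range-of-ranges is above its own cohort
    percentile.
    """

    def __init__(self, percentile: float = 90.0, combine: str = "and",
                 min_cohort_size: int = 8):
        self.percentile = percentile
        self.combine = combine
        self.min_cohort_size = min_cohort_size

    _required = ("lr_slice_range_of_ranges_mm", "ap_slice_range_of_ranges_mm")

    def fit(self, X: pd.DataFrame, y=None) -> "SliceExtentOutlierDetector":
        X = _as_frame(X, self._required)
        self._check_size(X)
        if not (0.0 < self.percentile < 100.0):
            raise MaskValidationError("percentile must be in (0, 100)")
        if self.combine not in ("and", "or"):
            raise MaskValidationError(f"combine must be 'and' or 'or', got {self.combine!r}")
        self.lr_threshold_ = percentile(
            X["lr_slice_range_of_ranges_mm"].to_numpy(), self.percentile
        )
        self.ap_threshold_ = percentile(
            X["ap_slice_range_of_ranges_mm"].to_numpy(), self.percentile
        )
        self.n_rows_ = len(X)
        return self

    def flag_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        X = _as_frame(X, self._required)
        with np.errstate(invalid="ignore"):
            lr_out = X["lr_slice_range_of_ranges_mm"].to_numpy(dtype=float) > self.lr_threshold_
            ap_out = X["ap_slice_range_of_ranges_mm"].to_numpy(dtype=float) > self.ap_threshold_
        flagged = (lr_out & ap_out) if self.combine == "and" else (lr_out | ap_out)
        return pd.DataFrame(
            {"lr_outlier": lr_out, "ap_outlier": ap_out, "flagged": flagged},
            index=X.index,
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.where(self.flag_frame(X)["flagged"].to_numpy(), -1, 1)

    def thresholds(self) -> dict:
        return {
            "lr_slice_range_of_ranges_mm_p{:g}".format(self.percentile): self.lr_threshold_,
            "ap_slice_range_of_ranges_mm_p{:g}".format(self.percentile): self.ap_threshold_,
            "combine": self.combine,
            "percentile_method": PERCENTILE_METHOD,
        }


# ---------------------------------------------------------------------------
# configuration and functional wrappers
# ---------------------------------------------------------------------------

@dataclass
class BladderConfig:
    volume_percentile: float = 25.0
    ratio_low_percentile: float = 10.0
    ratio_high_percentile: float = 90.0


@dataclass
class FemoralHeadConfig:
    volume_percentile: float = 20.0
    is_range_mm_threshold: float = 60.0
    lr_over_ap_ratio_threshold: float = 1.5


@dataclass
class SliceExtentConfig:
    percentile: float = 90.0
    combine: str = "and"


@dataclass
class ModelConfig:
    """Bundle of the three model configurations plus shared settings."""

    bladder: BladderConfig = field(default_factory=BladderConfig)
    femoral_head: FemoralHeadConfig = field(default_factory=FemoralHeadConfig)
    slice_extent: SliceExtentConfig = field(default_factory=SliceExtentConfig)
    percentile_method: str = PERCENTILE_METHOD
    min_cohort_size: int = 8

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            bladder=BladderConfig(**d.get("bladder", {})),
            femoral_head=FemoralHeadConfig(**d.get("femoral_head", {})),
            slice_extent=SliceExtentConfig(**d.get("slice_extent", {})),
            percentile_method=d.get("percentile_method", PERCENTILE_METHOD),
            min_cohort_size=d.get("min_cohort_size", 8),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d.get("models", d))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"models": self.to_dict()}, fh, sort_keys=True)


def load_default_config() -> ModelConfig:
    """Default model configuration shipped with the package."""
    from importlib.resources import files

    with (files("contourqa") / "default_config.yaml").open() as fh:
        d = yaml.safe_load(fh)
    return ModelConfig.from_dict(d.get("models", d))


@dataclass
class FlagReport:
    """Per-row flags plus the cohort thresholds that produced them."""

    model: str
    table: pd.DataFrame
    thresholds: dict

    @property
    def flagged(self) -> pd.Series:
        return self.table["flagged"]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "thresholds": self.thresholds,
            "rows": self.table.reset_index(drop=True).to_dict(orient="records"),
        }


def _attach_ids(flags: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    out = flags.copy()
    for col in ("patient_id", "roi_name"):
        if col in cohort.columns:
            out.insert(0, col, cohort[col])
    return out


def bladder_model(cohort: pd.DataFrame, config: ModelConfig | None = None) -> FlagReport:
    """Fit-and-apply the bladder emptiness detector on one cohort."""
    cfg = (config or ModelConfig())
    est = BladderEmptinessDetector(
        volume_percentile=cfg.bladder.volume_percentile,
        ratio_low_percentile=cfg.bladder.ratio_low_percentile,
        ratio_high_percentile=cfg.bladder.ratio_high_percentile,
        min_cohort_size=cfg.min_cohort_size,
    ).fit(cohort)
    return FlagReport("bladder", _attach_ids(est.flag_frame(cohort), cohort),
                      est.thresholds())


def femoral_head_model(cohort: pd.DataFrame, config: ModelConfig | None = None) -> FlagReport:
    """Fit-and-apply the femoral ball/shaft classifier; flag == ball_shaft."""
    cfg = (config or ModelConfig())
    est = FemoralHeadShaftClassifier(
        volume_percentile=cfg.femoral_head.volume_percentile,
        is_range_mm_threshold=cfg.femoral_head.is_range_mm_threshold,
        lr_over_ap_ratio_threshold=cfg.femoral_head.lr_over_ap_ratio_threshold,
        min_cohort_size=cfg.min_cohort_size,
    ).fit(cohort)
    labels = est.predict(cohort)
    table = pd.DataFrame(
        {"classification": labels, "flagged": labels == "ball_shaft"},
        index=cohort.index,
    )
    return FlagReport("femoral_head", _attach_ids(table, cohort), est.thresholds())


def slice_extent_model(cohort: pd.DataFrame, config: ModelConfig | None = None) -> FlagReport:
    """Fit-and-apply the slice-extent outlier detector on one cohort."""
    cfg = (config or ModelConfig())
    est = SliceExtentOutlierDetector(
        percentile=cfg.slice_extent.percentile,
        combine=cfg.slice_extent.combine,
        min_cohort_size=cfg.min_cohort_size,
    ).fit(cohort)
    return FlagReport("slice_extent", _attach_ids(est.flag_frame(cohort), cohort),
                      est.thresholds())
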