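"""Applicator-stability statistics from marker trajectories.

Converts pixel-space centroid trajectories into the millimetre-scale
quantities used to judge whether a light applicator holds its aim: per
subject, the horizontal/vertical displacement *range* (max - min) and sample
standard deviation over the recording; per cohort and intraoral position,
the mean +/- SD of those subject statistics and Tukey boxplot summaries
(25-75% bars, 1.5 x IQR whiskers, outliers beyond).

Displacements are referenced to the mean centroid over valid frames by
default (so they are centred at zero), with first-frame referencing
available. Pixel-to-millimetre calibration comes from the known physical
size of the ink mark; no other calibration source is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .exceptions import EmptyGroupError, InsufficientDataError, InvalidParameterError
from .tracking import Trajectory


class Position(str, Enum):
    """Intraoral applicator positions studied."""

    ANTERIOR_BUCCAL = "anterior_buccal"
    POSTERIOR_BUCCAL = "posterior_buccal"
    RETROMOLAR = "retromolar"


@dataclass
class CalibrationScale:
    """Pixel-to-millimetre conversion factor and its provenance."""

    pixels_per_mm: float
    method: str = "supplied"   # or "known_marker_size"

    def __post_init__(self):
        if not self.pixels_per_mm > 0:
            raise InvalidParameterError("pixels_per_mm must be > 0")


@dataclass
class SubjectStability:
    """One subject's displacement statistics at one position, in mm."""

    subject_id: str
    position: Position
    range_h_mm: float
    range_v_mm: float
    sd_h_mm: float
    sd_v_mm: float
    n_valid_frames: int
    outlier_frames: list[int] = field(default_factory=list)


@dataclass
class CohortSummary:
    """Cross-subject summary of one metric at one position."""

    position: Position
    metric: str                      # range_h | range_v | sd_h | sd_v
    mean: float
    sd: float
    n_subjects: int
    p25: float
    p75: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


def calibrate_pixels_per_mm(marker_extent_px: float,
                            marker_diameter_mm: float) -> CalibrationScale:
    """Scale from the pixel extent of an ink mark of known physical size."""
    if not marker_extent_px > 0 or not marker_diameter_mm > 0:
        raise InvalidParameterError("marker extent and diameter must be positive")
    return CalibrationScale(marker_extent_px / marker_diameter_mm,
                            method="known_marker_size")


def marker_extent_px(mask: np.ndarray, axis: str = "h") -> float:
    """Pixel extent (bounding-box width or height) of a marker mask."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if len(rows) == 0:
        raise InvalidParameterError("empty mask has no extent")
    coords = cols if axis == "h" else rows
    return float(coords.max() - coords.min() + 1)


def trajectory_displacements(traj: Trajectory, scale: CalibrationScale,
                             reference: str = "mean") -> pd.DataFrame:
    """Per-frame (dx_mm, dy_mm) displacements over the valid frames.

    ``reference="mean"`` subtracts the mean centroid over valid frames;
    ``"first"`` subtracts the first valid centroid. Invalid frames are
    omitted, not interpolated.
    """
    valid = traj.valid
    if valid.sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 valid frames, got {int(valid.sum())}")
    pts = traj.centroids[valid]
    if reference == "mean":
        ref = pts.mean(axis=0)
    elif reference == "first":
        ref = pts[0]
    else:
        raise InvalidParameterError(f"unknown reference {reference!r}")
    disp = (pts - ref) / scale.pixels_per_mm
    return pd.DataFrame({
        "frame": traj.frame_indices[valid],
        "time_s": traj.timestamps[valid],
        "dx_mm": disp[:, 0],
        "dy_mm": disp[:, 1],
    })


def _tukey_outlier_rows(values: np.ndarray) -> np.ndarray:
    p25, p75 = np.percentile(values, [25, 75])
    iqr = p75 - p25
    return (values < p25 - 1.5 * iqr) | (values > p75 + 1.5 * iqr)


def subject_stability(displacements: pd.DataFrame, subject_id: str = "",
                      position: Position | str = Position.ANTERIOR_BUCCAL,
                      range_mode: str = "minmax") -> SubjectStability:
    """Range and sample SD of each displacement component for one subject.

    ``range_mode="minmax"`` (default) takes max - min of the component;
    ``"maxabs"`` takes the peak absolute deviation instead. SDs use the n-1
    denominator. Frames beyond the Tukey 1.5 x IQR fences on either component
    (swallows and other oral-cavity motion) are listed in
    ``outlier_frames`` but are *not* removed from the statistics.
    """
    dx = displacements["dx_mm"].to_numpy(float)
    dy = displacements["dy_mm"].to_numpy(float)
    if len(dx) < 2:
        raise InsufficientDataError("need >= 2 valid frames")
    if range_mode == "minmax":
        range_h, range_v = np.ptp(dx), np.ptp(dy)
    elif range_mode == "maxabs":
        range_h, range_v = np.abs(dx).max(), np.abs(dy).max()
    else:
        raise InvalidParameterError(f"unknown range_mode {range_mode!r}")
    outlier_rows = _tukey_outlier_rows(dx) | _tukey_outlier_rows(dy)
    return SubjectStability(
        subject_id=subject_id,
        position=Position(position),
        range_h_mm=float(range_h),
        range_v_mm=float(range_v),
        sd_h_mm=float(np.std(dx, ddof=1)),
        sd_v_mm=float(np.std(dy, ddof=1)),
        n_valid_frames=len(dx),
        outlier_frames=[int(f) for f in displacements["frame"].to_numpy()[outlier_rows]],
    )


_METRIC_FIELD = {"range_h": "range_h_mm", "range_v": "range_v_mm",
                 "sd_h": "sd_h_mm", "sd_v": "sd_v_mm"}


def cohort_summary(stabilities: list[SubjectStability], metric: str,
                   position: Position | str) -> CohortSummary:
    """Mean +/- sample SD of one metric across a position's subjects.

    Also computes Tukey boxplot statistics: 25th/75th percentiles (linear
    interpolation), whiskers at the most extreme values within 1.5 x IQR of
    the quartiles, and the values beyond them as outliers. Requires at least
    two subjects in the group.
    """
    if metric not in _METRIC_FIELD:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    position = Position(position)
    values = np.array([getattr(s, _METRIC_FIELD[metric]) for s in stabilities
                       if s.position == position], dtype=float)
    if len(values) == 0:
        raise EmptyGroupError(f"no subjects at position {position.value}")
    if len(values) < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects at {position.value}, got {len(values)}")
    p25, p75 = np.percentile(values, [25, 75])
    iqr = p75 - p25
    lo_fence, hi_fence = p25 - 1.5 * iqr, p75 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return CohortSummary(
        position=position, metric=metric,
        mean=float(values.mean()), sd=float(np.std(values, ddof=1)),
        n_subjects=len(values),
        p25=float(p25), p75=float(p75),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in outliers),
    )


def summarize_cohort(stabilities: list[SubjectStability]) -> pd.DataFrame:
    """All (position, metric) cohort summaries present in the data, as a table."""
    rows = []
    for position in Position:
        if not any(s.position == position for s in stabilities):
            continue
        for metric in _METRIC_FIELD:
            c = cohort_summary(stabilities, metric, position)
            rows.append({
                "position": position.value, "metric": metric,
                "mean_mm": c.mean, "sd_mm": c.sd, "n_subjects": c.n_subjects,
                "p25_mm": c.p25, "p75_mm": c.p75,
                "n_outliers": len(c.outliers),
            })
    return pd.DataFrame(rows)


def plot_displacement_boxplots(displacements_by_subject: dict[str, pd.DataFrame],
                               component: str = "dx_mm", ax=None):
    """Per-subject displacement boxplots (25-75% bars, mean marker, outliers).

    Mirrors the cohort stability figures: one box per subject, Tukey
    whiskers, outlier points shown as black circles, a marker at the mean.
    Returns the matplotlib Axes.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(displacements_by_subject) + 2, 4))
    labels = list(displacements_by_subject)
    data = [displacements_by_subject[s][component].to_numpy() for s in labels]
    ax.boxplot(data, tick_labels=labels, whis=1.5, showmeans=True,
               flierprops={"marker": "o", "markerfacecolor": "k", "markersize": 3})
    ax.set_ylabel({"dx_mm": "horizontal displacement (mm)",
                   "dy_mm": "vertical displacement (mm)"}.get(component, component))
    ax.axhline(0.0, color="0.7", lw=0.8, zorder=0)
    return ax
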