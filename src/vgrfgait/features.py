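"""The 13 per-subject gait features computed from segmented VGRF cycles.

Feature set (fixed column order, version 1):

1.  cv_swing        — coefficient of variation of per-cycle swing time (%)
2.  cv_stride       — coefficient of variation of per-cycle stride time (%)
3.  mean_cop_x      — mean centre-of-pressure x over all stance frames
4.  sd_cop_x        — sample SD of centre-of-pressure x over stance frames
5.  mean_cop_y      — mean centre-of-pressure y
6.  sd_cop_y        — sample SD of centre-of-pressure y
7.  mean_pf_heel    — mean over cycles of the heel-strike peak force (N)
8.  mean_pf_toe     — mean over cycles of the toe-off peak force (N)
9.  sd_pf_heel      — SD over cycles of the heel-strike peak force (N)
10. sd_pf_toe       — SD over cycles of the toe-off peak force (N)
11. mean_kurtosis   — mean over cycles of the stance-waveform kurtosis
12. mean_skewness   — mean over cycles of the stance-waveform skewness
13. mean_peak_power — mean over cycles of the peak spectral power (dB)

The heel-strike (toe-off) peak is the maximum of the summed force over
the heel-role (toe-role) sensors within the first (last) five stance
samples — 50 ms at 100 Hz.  CoP coordinates are the force-weighted mean
sensor positions, pooled over every stance frame of every cycle.

Two CV conventions are supported.  ``standard`` is the usual
100·SD/mean of gait-variability research and the default; ``reciprocal``
computes the reciprocal 100·mean/SD, which some reports print.  Both
use the sample (n−1) standard deviation.  Kurtosis is the Pearson
(non-excess, normal → 3) form and skewness the standardized third
moment, both with population (n) normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io import SensorLayout, VGRFRecord, default_layout
from .preprocess import (DEFAULT_NOISE_FLOOR, DEFAULT_STRIDE_BOUNDS,
                         DEFAULT_SWING_FRACTION_BOUNDS, DEFAULT_TRIM_SECONDS,
                         GaitCycle, PreprocessResult, preprocess_record)

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = (
    "cv_swing", "cv_stride",
    "mean_cop_x", "sd_cop_x", "mean_cop_y", "sd_cop_y",
    "mean_pf_heel", "mean_pf_toe", "sd_pf_heel", "sd_pf_toe",
    "mean_kurtosis", "mean_skewness", "mean_peak_power",
)

LABEL_CODES = {"control": 0, "pd": 1}


class DegenerateFeatureError(ValueError):
    """A feature is undefined on this input (e.g. zero variance)."""


@dataclass
class FeatureConfig:
    """Knobs of the feature-extraction stage (defaults mirror the pipeline)."""

    noise_floor: float = DEFAULT_NOISE_FLOOR
    trim_seconds: float = DEFAULT_TRIM_SECONDS
    stride_bounds: tuple[float, float] = DEFAULT_STRIDE_BOUNDS
    swing_fraction_bounds: tuple[float, float] = DEFAULT_SWING_FRACTION_BOUNDS
    cycle_order: str = "stance_first"
    cv_convention: str = "standard"   # "standard" (SD/mean) | "reciprocal" (mean/SD)
    peak_window: int = 5              # stance samples examined at heel strike / toe off
    peak_mode: str = "summed"         # "summed" role sensors | "per_sensor" max
    shape_scope: str = "stance"       # "stance" | "cycle" for kurtosis/skewness
    min_cycles: int = 5               # subjects with fewer usable cycles are skipped


@dataclass
class FeatureVector:
    subject_id: str
    group: str
    n_cycles: int
    values: dict[str, float] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# Individual features
# ---------------------------------------------------------------------------

def coefficient_of_variation(values, convention: str = "standard") -> float:
    """Coefficient of variation of a list of durations, in percent.

    ``standard``: 100·SD/mean; ``reciprocal``: 100·mean/SD.  SD is the
    sample (n−1) standard deviation.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = values.mean()
    sd = values.std(ddof=1)
    if convention == "standard":
        if mean == 0:
            raise DegenerateFeatureError("CV undefined: mean is zero")
        return 100.0 * sd / mean
    if convention == "reciprocal":
        if sd == 0:
            raise DegenerateFeatureError("reciprocal CV undefined: SD is zero")
        return 100.0 * mean / sd
    raise ValueError(f"unknown CV convention {convention!r}")


def swing_stride_cv(cycles: list[GaitCycle], convention: str = "standard") -> tuple[float, float]:
    """(cv_swing, cv_stride) over the per-cycle swing and stride times."""
    if len(cycles) < 2:
        raise ValueError("need at least 2 cycles for timing variability")
    swing = [c.swing_time for c in cycles]
    stride = [c.stride_time for c in cycles]
    return (coefficient_of_variation(swing, convention),
            coefficient_of_variation(stride, convention))


def cop_point(frame_forces: np.ndarray, layout: SensorLayout, axis: str,
              foot: str = "left") -> float:
    """Force-weighted mean sensor coordinate at one time instant.

    CoP_axis = Σᵢ sᵢ·fᵢ / Σᵢ fᵢ over the foot's 8 sensors.
    """
    frame_forces = np.asarray(frame_forces, dtype=float)
    total = frame_forces.sum()
    if total <= 0:
        raise DegenerateFeatureError("CoP undefined on a zero-force frame")
    coords = layout.coordinates(foot, axis)
    return float(np.dot(coords, frame_forces) / total)


def cop_summary(cycles: list[GaitCycle], sensor_series: np.ndarray,
                layout: SensorLayout, foot: str = "left") -> tuple[float, float, float, float]:
    """(mean_cop_x, sd_cop_x, mean_cop_y, sd_cop_y) pooled over stance frames.

    The CoP is evaluated at every stance sample of every cycle and the
    mean and sample SD are taken over the pooled per-sample values (not
    over per-cycle means).
    """
    if not cycles:
        raise ValueError("cop_summary needs at least one cycle")
    frames = np.vstack([sensor_series[a:b] for c in cycles for (a, b) in [c.stance]])
    totals = frames.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateFeatureError("zero-force frame inside a stance range")
    out = []
    for axis in ("x", "y"):
        coords = layout.coordinates(foot, axis)
        cop = frames @ coords / totals
        out.extend([float(cop.mean()), float(cop.std(ddof=1)) if len(cop) > 1 else 0.0])
    return tuple(out)  # type: ignore[return-value]


def peak_phase_force(cycle: GaitCycle, sensor_series: np.ndarray,
                     role_columns: np.ndarray, phase: str = "heel",
                     window: int = 5, mode: str = "summed") -> float:
    """Peak role-sensor force around heel strike or toe off of one cycle.

    ``heel``: the first ``window`` stance samples; ``toe``: the last
    ``window``.  With ``mode='summed'`` the role sensors' forces are
    summed per frame before taking the max; ``per_sensor`` takes the max
    over individual sensors instead.  A stance shorter than the window
    falls back to the full stance (logged).
    """
    a, b = cycle.stance
    if b - a < window:
        logger.warning("stance of %d samples shorter than peak window %d; using full stance",
                       b - a, window)
        sl = slice(a, b)
    else:
        sl = slice(a, a + window) if phase == "heel" else slice(b - window, b)
    frames = sensor_series[sl][:, role_columns]
    if mode == "summed":
        return float(frames.sum(axis=1).max())
    if mode == "per_sensor":
        return float(frames.max())
    raise ValueError(f"unknown peak mode {mode!r}")


def cycle_shape_stats(cycle: GaitCycle, total_series: np.ndarray,
                      scope: str = "stance") -> tuple[float, float]:
    """(kurtosis, skewness) of the total-force waveform within one cycle.

    Pearson kurtosis (normal → 3) and standardized skewness, both with
    population (n) normalization, over the stance samples (default) or
    the full cycle including swing zeros (``scope='cycle'``).
    """
    if scope == "stance":
        a, b = cycle.stance
    elif scope == "cycle":
        a, b = cycle.start, cycle.end
    else:
        raise ValueError(f"unknown shape scope {scope!r}")
    x = np.asarray(total_series[a:b], dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples for shape statistics")
    if np.ptp(x) == 0:
        raise DegenerateFeatureError("shape statistics undefined on a constant segment")
    kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    skew = float(stats.skew(x, bias=True))
    return kurt, skew


def peak_psd_power_db(cycle: GaitCycle, total_series: np.ndarray,
                      sampling_rate: float) -> float:
    """Peak power spectral density of one cycle's total-force segment, in dB.

    Single-segment periodogram (rectangular window, one-sided, density
    scaling) over the full cycle; the feature is 10·log10 of the PSD
    maximum.  Cycles are ~1 s (≈100 samples at 100 Hz), too short for
    multi-segment averaging.
    """
    x = np.asarray(total_series[cycle.start:cycle.end], dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 samples for a spectral estimate")
    if not np.any(x):
        raise DegenerateFeatureError("peak PSD undefined on an all-zero segment")
    _, psd = signal.periodogram(x, fs=sampling_rate, window="boxcar", scaling="density")
    return float(10.0 * np.log10(psd.max()))


# ---------------------------------------------------------------------------
# Per-subject extraction
# ---------------------------------------------------------------------------

def features_from_preprocessed(pre: PreprocessResult, layout: SensorLayout,
                               foot: str, config: FeatureConfig,
                               subject_id: str, group: str) -> FeatureVector | None:
    """Assemble the 13-feature vector from a preprocessed foot."""
    cycles = pre.cycles
    if len(cycles) < config.min_cycles:
        logger.warning("subject %s skipped: %d usable cycles < minimum %d",
                       subject_id, len(cycles), config.min_cycles)
        return None

    cv_swing, cv_stride = swing_stride_cv(cycles, config.cv_convention)
    mean_x, sd_x, mean_y, sd_y = cop_summary(cycles, pre.sensor_forces, layout, foot)

    heel_cols = layout.role_columns(foot, "heel")
    toe_cols = layout.role_columns(foot, "toe")
    heel_peaks = [peak_phase_force(c, pre.sensor_forces, heel_cols, "heel",
                                   config.peak_window, config.peak_mode) for c in cycles]
    toe_peaks = [peak_phase_force(c, pre.sensor_forces, toe_cols, "toe",
                                  config.peak_window, config.peak_mode) for c in cycles]
    shape = [cycle_shape_stats(c, pre.total, config.shape_scope) for c in cycles]
    power = [peak_psd_power_db(c, pre.total, pre.sampling_rate) for c in cycles]

    heel_peaks = np.array(heel_peaks)
    toe_peaks = np.array(toe_peaks)
    values = {
        "cv_swing": cv_swing,
        "cv_stride": cv_stride,
        "mean_cop_x": mean_x, "sd_cop_x": sd_x,
        "mean_cop_y": mean_y, "sd_cop_y": sd_y,
        "mean_pf_heel": float(heel_peaks.mean()),
        "mean_pf_toe": float(toe_peaks.mean()),
        "sd_pf_heel": float(heel_peaks.std(ddof=1)),
        "sd_pf_toe": float(toe_peaks.std(ddof=1)),
        "mean_kurtosis": float(np.mean([k for k, _ in shape])),
        "mean_skewness": float(np.mean([s for _, s in shape])),
        "mean_peak_power": float(np.mean(power)),
    }
    for name, v in values.items():
        if not np.isfinite(v):
            raise DegenerateFeatureError(f"feature {name} is not finite for {subject_id}")
    return FeatureVector(subject_id=subject_id, group=group,
                         n_cycles=len(cycles), values=values)


def extract_features(record: VGRFRecord, side: str = "left",
                     layout: SensorLayout | None = None,
                     config: FeatureConfig | None = None) -> FeatureVector | None:
    """Preprocess one record and compute its 13-feature vector.

    Returns ``None`` (with a logged reason) when fewer than
    ``config.min_cycles`` usable cycles survive segmentation.  A pure
    function of (record, layout, config): repeated runs are bit-identical.
    """
    layout = layout or default_layout()
    config = config or FeatureConfig()
    pre = preprocess_record(record, side=side, floor=config.noise_floor,
                            trim_seconds=config.trim_seconds,
                            stride_bounds=config.stride_bounds,
                            swing_fraction_bounds=config.swing_fraction_bounds,
                            cycle_order=config.cycle_order)
    return features_from_preprocessed(pre, layout, side, config,
                                      record.subject_id, record.group)


def feature_table(records, side: str = "left", layout: SensorLayout | None = None,
                  config: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per subject that yields a vector.

    Columns: the 13 features in fixed order, then subject_id, group,
    n_cycles.  Subjects with too few cycles are skipped (logged).
    """
    layout = layout or default_layout()
    config = config or FeatureConfig()
    rows = []
    for record in records:
        vec = extract_features(record, side=side, layout=layout, config=config)
        if vec is None:
            continue
        row = dict(vec.values)
        row.update(subject_id=vec.subject_id, group=vec.group, n_cycles=vec.n_cycles)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES) + ["subject_id", "group", "n_cycles"])
    return df


def split_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, feature_names) from a feature table; labels control=0, pd=1."""
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = table["group"].map(LABEL_CODES).to_numpy(dtype=int)
    return X, y, list(FEATURE_NAMES)
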