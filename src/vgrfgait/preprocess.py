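"""Noise flooring, gait-initiation trimming and stride-cycle segmentation.

The total vertical force under one foot alternates between runs of
positive values (stance: the foot loads the ground) and runs of zeros
(swing: the foot is airborne) once sub-threshold sensor noise has been
floored to zero.  A stride cycle spans one heel strike to the next, i.e.
a stance run followed by its swing run, closed by the next stance onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io import VGRFRecord

logger = logging.getLogger(__name__)

DEFAULT_NOISE_FLOOR = 20.0   # newtons
DEFAULT_TRIM_SECONDS = 20.0  # gait-initiation transient discarded at the front
DEFAULT_STRIDE_BOUNDS = (0.4, 4.0)        # seconds, generous for human walking
DEFAULT_SWING_FRACTION_BOUNDS = (0.05, 0.70)


@dataclass(frozen=True)
class GaitCycle:
    """One stride as two contiguous half-open sample ranges.

    Under the default stance-first convention (heel strike to next heel
    strike) ``stance = [start, split)`` and ``swing = [split, end)``;
    with ``stance_first=False`` the phases swap.  Either way
    ``stride_time = stance_time + swing_time = (end - start) / fs``.
    """

    start: int
    split: int
    end: int
    sampling_rate: float
    stance_first: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.split < self.end:
            raise ValueError("phase ranges must be contiguous and non-empty")

    @property
    def stance(self) -> tuple[int, int]:
        return (self.start, self.split) if self.stance_first else (self.split, self.end)

    @property
    def swing(self) -> tuple[int, int]:
        return (self.split, self.end) if self.stance_first else (self.start, self.split)

    @property
    def stance_start(self) -> int:
        return self.stance[0]

    @property
    def stance_time(self) -> float:
        a, b = self.stance
        return (b - a) / self.sampling_rate

    @property
    def swing_time(self) -> float:
        a, b = self.swing
        return (b - a) / self.sampling_rate

    @property
    def stride_time(self) -> float:
        return (self.end - self.start) / self.sampling_rate

    @property
    def swing_fraction(self) -> float:
        return self.swing_time / self.stride_time


def floor_noise(series: np.ndarray, floor: float = DEFAULT_NOISE_FLOOR) -> np.ndarray:
    """Zero every sample strictly below ``floor`` newtons.

    The comparison is strict, so a sample exactly at the floor survives.
    Idempotent; works on 1-D series and (n, 8) sensor arrays alike.
    """
    if floor < 0:
        raise ValueError("noise floor must be nonnegative")
    series = np.asarray(series, dtype=float)
    return np.where(series < floor, 0.0, series)


def trim_initiation(record: VGRFRecord, trim_seconds: float = DEFAULT_TRIM_SECONDS) -> VGRFRecord:
    """Drop the first ``trim_seconds`` of a record (gait-initiation transient)."""
    if trim_seconds < 0:
        raise ValueError("trim_seconds must be nonnegative")
    n_trim = int(round(trim_seconds * record.sampling_rate))
    if n_trim >= record.n_samples:
        raise ValueError(
            f"record too short: {record.duration:.1f} s <= trim of {trim_seconds} s")
    if n_trim == 0:
        return record
    return replace(
        record,
        time=record.time[n_trim:],
        left_forces=record.left_forces[n_trim:],
        right_forces=record.right_forces[n_trim:],
        left_total=record.left_total[n_trim:],
        right_total=record.right_total[n_trim:],
        warnings=list(record.warnings),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of a boolean mask as (start, stop, value) half-open triples."""
    if len(mask) == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(mask)]])
    return [(int(a), int(b), bool(mask[a])) for a, b in zip(starts, stops)]


def segment_cycles(total: np.ndarray, sampling_rate: float,
                   stride_bounds: tuple[float, float] = DEFAULT_STRIDE_BOUNDS,
                   swing_fraction_bounds: tuple[float, float] = DEFAULT_SWING_FRACTION_BOUNDS,
                   cycle_order: str = "stance_first") -> list[GaitCycle]:
    """Segment a floored total-force series into complete stride cycles.

    A complete cycle under the default ``stance_first`` convention is a
    maximal positive run (stance) followed by a maximal zero run (swing)
    that is itself closed by the next positive sample — heel strike to
    heel strike.  Incomplete material is discarded: a leading zero run, a
    stance run starting at sample 0 (its true onset precedes the series),
    and any trailing stance or unclosed swing.  ``swing_first`` instead
    pairs each zero run with the following positive run.

    Cycles whose stride time falls outside ``stride_bounds`` (seconds) or
    whose swing fraction falls outside ``swing_fraction_bounds`` are
    dropped and logged — residual noise can otherwise fabricate
    single-sample stances.
    """
    if cycle_order not in ("stance_first", "swing_first"):
        raise ValueError(f"unknown cycle_order {cycle_order!r}")
    total = np.asarray(total, dtype=float)
    runs = _runs(total > 0)

    want_first = cycle_order == "stance_first"
    lo, hi = stride_bounds
    flo, fhi = swing_fraction_bounds

    cycles: list[GaitCycle] = []
    n_dropped = 0
    # runs alternate, so runs[i] and runs[i+1] are always opposite phases;
    # requiring runs[i+2] to exist closes the cycle with the next onset.
    for i in range(len(runs) - 2):
        a_start, a_stop, a_pos = runs[i]
        _, b_stop, _ = runs[i + 1]
        if a_pos is not want_first:
            continue
        if a_start == 0:
            continue  # true onset of the first run precedes the series
        cycle = GaitCycle(a_start, a_stop, b_stop, sampling_rate, stance_first=want_first)
        if not (lo <= cycle.stride_time <= hi) or not (flo <= cycle.swing_fraction <= fhi):
            n_dropped += 1
            continue
        cycles.append(cycle)
    if n_dropped:
        logger.info("segment_cycles: dropped %d cycle(s) outside sanity bounds", n_dropped)
    return cycles


@dataclass
class PreprocessResult:
    """Cycles plus the floored per-sensor series on the trimmed time base."""

    cycles: list[GaitCycle]
    sensor_forces: np.ndarray  # (n_trimmed, 8), floored
    total: np.ndarray          # (n_trimmed,), sum of floored sensors
    time: np.ndarray           # (n_trimmed,)
    sampling_rate: float


def preprocess_record(record: VGRFRecord, side: str = "left",
                      floor: float = DEFAULT_NOISE_FLOOR,
                      trim_seconds: float = DEFAULT_TRIM_SECONDS,
                      stride_bounds: tuple[float, float] = DEFAULT_STRIDE_BOUNDS,
                      swing_fraction_bounds: tuple[float, float] = DEFAULT_SWING_FRACTION_BOUNDS,
                      cycle_order: str = "stance_first") -> PreprocessResult:
    """Floor, trim and segment one foot of a record.

    The analysis total is the sum of the eight floored per-sensor series
    (flooring is applied per sensor, before summation).
    """
    trimmed = trim_initiation(record, trim_seconds)
    sensors = floor_noise(trimmed.forces(side), floor)
    total = sensors.sum(axis=1)
    cycles = segment_cycles(total, record.sampling_rate, stride_bounds,
                            swing_fraction_bounds, cycle_order)
    return PreprocessResult(cycles=cycles, sensor_forces=sensors, total=total,
                            time=trimmed.time, sampling_rate=record.sampling_rate)
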