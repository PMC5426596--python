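"""Reading and writing VGRF gait records and cohort manifests.

Records follow the plain-text dialect of the public PhysioNet gait
databases: one row per sample, 19 whitespace/tab-separated numeric
columns — time in seconds, eight left-insole sensor forces, eight
right-insole sensor forces, and the per-foot total forces, all in
newtons, typically sampled at 100 Hz.

Conventions used throughout the package: forces in newtons, times in
seconds, 0-based sample indices, half-open index ranges.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

N_SENSORS = 8
N_COLUMNS = 19  # time + 8 left + 8 right + left total + right total
TOTAL_CONSISTENCY_TOL = 0.5  # newtons, per sample
GROUPS = ("control", "pd")


class FormatError(ValueError):
    """Raised when a record or layout file violates the expected format."""


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sensor:
    sensor_id: int
    foot: str          # "left" | "right"
    x: float           # arbitrary planar units, origin between the feet
    y: float           # positive y = walking direction
    role: str          # "heel" | "midfoot" | "toe"


@dataclass(frozen=True)
class SensorLayout:
    """Planar coordinates and heel/midfoot/toe role tags of the insole sensors.

    Exactly eight sensors per foot; under the default frame the left
    foot occupies x <= 0 and the right foot x >= 0, heel sensors have
    strictly smaller y than toe sensors (the subject faces +y).
    """

    sensors: tuple[Sensor, ...]

    def __post_init__(self) -> None:
        for foot in ("left", "right"):
            sensors = self.foot_sensors(foot)
            if len(sensors) != N_SENSORS:
                raise FormatError(
                    f"layout must have exactly {N_SENSORS} {foot}-foot sensors, "
                    f"got {len(sensors)}"
                )
            ids = [s.sensor_id for s in sensors]
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate sensor_id on {foot} foot")
            roles = {s.role for s in sensors}
            if not roles <= {"heel", "midfoot", "toe"}:
                raise FormatError(f"unknown sensor role in {roles}")
            if "heel" not in roles or "toe" not in roles:
                raise FormatError(f"{foot} foot needs at least one heel and one toe sensor")
            heel_y = max(s.y for s in sensors if s.role == "heel")
            toe_y = min(s.y for s in sensors if s.role == "toe")
            if not heel_y < toe_y:
                raise FormatError("heel sensors must lie at strictly smaller y than toe sensors")
        if any(s.x > 0 for s in self.foot_sensors("left")):
            raise FormatError("left-foot sensors must have x <= 0")
        if any(s.x < 0 for s in self.foot_sensors("right")):
            raise FormatError("right-foot sensors must have x >= 0")

    def foot_sensors(self, foot: str) -> tuple[Sensor, ...]:
        """Sensors of one foot, ordered by sensor_id (the record column order)."""
        return tuple(sorted((s for s in self.sensors if s.foot == foot),
                            key=lambda s: s.sensor_id))

    def coordinates(self, foot: str, axis: str) -> np.ndarray:
        """Length-8 coordinate vector for one foot along ``axis`` ('x'|'y')."""
        return np.array([getattr(s, axis) for s in self.foot_sensors(foot)], dtype=float)

    def role_columns(self, foot: str, role: str) -> np.ndarray:
        """0-based column indices (within the foot's 8 series) of one role."""
        return np.array([i for i, s in enumerate(self.foot_sensors(foot))
                         if s.role == role], dtype=int)


def _layout_from_mapping(doc: dict) -> SensorLayout:
    try:
        raw = doc["sensors"]
    except (TypeError, KeyError):
        raise FormatError("layout file must contain a 'sensors' list")
    entries = []
    for item in raw:
        entries.append(dict(item))
    # assign roles by y extremes per foot when not given explicitly
    for foot in ("left", "right"):
        foot_items = [e for e in entries if e.get("foot") == foot]
        if foot_items and not all("role" in e for e in foot_items):
            ys = [float(e["y"]) for e in foot_items]
            y_min, y_max = min(ys), max(ys)
            for e in foot_items:
                y = float(e["y"])
                e["role"] = "heel" if y == y_min else "toe" if y == y_max else "midfoot"
    sensors = tuple(Sensor(sensor_id=int(e["sensor_id"]), foot=str(e["foot"]),
                           x=float(e["x"]), y=float(e["y"]), role=str(e["role"]))
                    for e in entries)
    return SensorLayout(sensors)


def load_layout(path: str | Path) -> SensorLayout:
    """Load a sensor layout from a YAML file, validating its invariants.

    Roles may be omitted, in which case the sensor(s) with minimum y per
    foot are tagged heel, the maximum-y sensor(s) toe, the rest midfoot.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _layout_from_mapping(doc)


def default_layout() -> SensorLayout:
    """The built-in versioned insole layout (see ``data/default_layout.yaml``)."""
    ref = resources.files("vgrfgait.data").joinpath("default_layout.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _layout_from_mapping(doc)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class VGRFRecord:
    """One subject-walk of per-sensor vertical ground reaction forces.

    ``left_forces`` and ``right_forces`` are (n_samples, 8) arrays in
    newtons, column i holding sensor_id i+1.  ``warnings`` collects
    consistency problems found at parse time (the record is still
    usable).
    """

    subject_id: str
    group: str                # "control" | "pd"
    sampling_rate: float      # Hz
    time: np.ndarray          # (n,) seconds, strictly increasing
    left_forces: np.ndarray   # (n, 8) N
    right_forces: np.ndarray  # (n, 8) N
    left_total: np.ndarray    # (n,) N
    right_total: np.ndarray   # (n,) N
    warnings: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def forces(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return self.left_forces if side == "left" else self.right_forces

    def validate(self) -> None:
        n = self.n_samples
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        for name in ("left_forces", "right_forces"):
            arr = getattr(self, name)
            if arr.shape != (n, N_SENSORS):
                raise FormatError(f"{name} must have shape ({n}, {N_SENSORS})")
            if np.any(arr < 0):
                raise FormatError(f"{name} contains negative forces")
        for name in ("left_total", "right_total"):
            if getattr(self, name).shape != (n,):
                raise FormatError(f"{name} must have length {n}")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise FormatError("time must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sampling_rate, atol=1e-4):
                raise FormatError("time spacing inconsistent with sampling_rate")


def _check_totals(record: VGRFRecord) -> None:
    for side in ("left", "right"):
        total = getattr(record, f"{side}_total")
        sensor_sum = record.forces(side).sum(axis=1)
        bad = np.abs(total - sensor_sum) > TOTAL_CONSISTENCY_TOL
        if np.any(bad):
            msg = (f"{side}_total deviates from the sensor sum by more than "
                   f"{TOTAL_CONSISTENCY_TOL} N on {int(bad.sum())} sample(s) "
                   f"(first at row {int(np.argmax(bad))})")
            record.warnings.append(msg)
            logger.warning("%s: %s", record.subject_id, msg)


def read_record(path: str | Path, layout: SensorLayout | None = None,
                sampling_rate: float = 100.0, subject_id: str | None = None,
                group: str = "control") -> VGRFRecord:
    """Parse one 19-column VGRF text record.

    Negative force readings are clamped to zero (and logged); a per-foot
    total that disagrees with the sum of its eight sensors by more than
    0.5 N appends a consistency warning to the returned record.  Rows
    with non-numeric fields or the wrong column count raise
    :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError:
        # re-scan to report the first offending 1-based line number
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if not fields:
                    continue
                try:
                    [float(f) for f in fields]
                except ValueError:
                    raise FormatError(f"{path}: non-numeric field on line {lineno}")
                if len(fields) != N_COLUMNS:
                    raise FormatError(
                        f"{path}: expected {N_COLUMNS} columns, got {len(fields)} "
                        f"on line {lineno}")
        raise FormatError(f"{path}: malformed numeric text")
    if data.size == 0:
        raise FormatError(f"{path}: empty record file")
    if data.shape[1] != N_COLUMNS:
        raise FormatError(f"{path}: expected {N_COLUMNS} columns, got {data.shape[1]}")

    time = data[:, 0]
    left = data[:, 1:9]
    right = data[:, 9:17]
    left_total = data[:, 17]
    right_total = data[:, 18]

    warnings: list[str] = []
    for name, arr in (("left", left), ("right", right),
                      ("left_total", left_total), ("right_total", right_total)):
        neg = arr < 0
        if np.any(neg):
            msg = f"{int(neg.sum())} negative {name} force sample(s) clamped to 0"
            warnings.append(msg)
            logger.warning("%s: %s", path, msg)
            np.clip(arr, 0.0, None, out=arr)

    record = VGRFRecord(
        subject_id=subject_id or path.stem,
        group=group,
        sampling_rate=sampling_rate,
        time=time, left_forces=left, right_forces=right,
        left_total=left_total, right_total=right_total,
        warnings=warnings,
    )
    record.validate()
    _check_totals(record)
    return record


def write_record(record: VGRFRecord, path: str | Path) -> Path:
    """Write a record in the 19-column dialect (tab-separated, 6 decimals).

    ``read_record(write_record(r))`` reproduces every force and time value
    to within 1e-6 N / s.  Refuses to write a record with zero samples.
    """
    if record.n_samples == 0:
        raise FormatError("refusing to write a record with zero samples")
    record.validate()
    path = Path(path)
    data = np.column_stack([record.time, record.left_forces, record.right_forces,
                            record.left_total, record.right_total])
    np.savetxt(path, data, fmt="%.6f", delimiter="\t")
    return path


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject_id: str
    group: str


@dataclass
class CohortManifest:
    """Maps record files to subject ids and group labels."""

    entries: list[ManifestEntry]
    layout_path: str | None = None

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise FormatError("subject_ids in manifest must be unique")
        for e in self.entries:
            if e.group not in GROUPS:
                raise FormatError(f"group must be one of {GROUPS}, got {e.group!r}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest from CSV (columns path,subject_id,group) or YAML."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = [ManifestEntry(str(e["path"]), str(e["subject_id"]), str(e["group"]))
                   for e in doc["records"]]
        return CohortManifest(entries, layout_path=doc.get("layout"))
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        entries = [ManifestEntry(row["path"], row["subject_id"], row["group"])
                   for row in reader]
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "subject_id", "group"])
        for e in manifest.entries:
            writer.writerow([e.path, e.subject_id, e.group])
    return path


def load_cohort(manifest: CohortManifest, layout: SensorLayout | None = None,
                sampling_rate: float = 100.0,
                base_dir: str | Path | None = None) -> list[VGRFRecord]:
    """Read every record listed in a manifest, attaching labels."""
    records = []
    for entry in manifest:
        p = Path(entry.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing record file: {p}")
        records.append(read_record(p, layout=layout, sampling_rate=sampling_rate,
                                   subject_id=entry.subject_id, group=entry.group))
    return records
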