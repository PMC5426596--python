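"""Synthetic VGRF cohort generator with per-stride ground truth.

Generates labeled control/PD walks with the statistical structure the
analysis pipeline assumes: two-minute-plus records sampled at 100 Hz,
eight sensors per foot at fixed planar coordinates, alternating stance
and swing, group contrasts in stride/swing-time variability, heel and
toe peak forces and centre-of-pressure excursion, and sub-floor (< 20 N)
spurious sensor blips during swing.  Every simulated stride is reported
back as ground truth (boundaries, realized times, programmed peaks,
per-frame CoP), so each pipeline stage can be validated against what
was actually generated.

Waveform model, per stride of m stance samples:

* heel-role sensors ramp up over the first 5 samples with a quarter-sine
  rise that peaks at ``heel_peak`` on stance sample 4 (50 ms at 100 Hz)
  and decays with a raised cosine over roughly a third of stance;
* toe-role sensors mirror the heel shape at the end of stance, peaking
  at ``toe_peak`` 50 ms before toe off;
* midfoot sensors share a Tukey-window plateau normalized per frame to
  ``body_force``, with a heel→toe sweep of the per-sensor weights whose
  modulation depth ``cop_y_excursion`` controls how far the CoP
  travels along the foot (small depth ≈ flat-footed loading).

The first and last stance samples carry substantial force (≈ 30 % of
the heel/toe peak), so with noise disabled the 20 N flooring recovers
every programmed boundary exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal.windows import tukey

from .io import (CohortManifest, ManifestEntry, SensorLayout, VGRFRecord,
                 default_layout, write_manifest, write_record)

STRIDE_TRUNCATION = (0.4, 2.5)  # s, truncation of the stride-time draw
RISE_SAMPLES = 4                # heel peak lands on stance sample 4 (50 ms)


@dataclass(frozen=True)
class GaitProfile:
    """Statistical gait profile of one group.

    Defaults describe an unimpaired adult walking at natural pace:
    1.1 s strides with 4 % timing variability, 38 % swing fraction,
    a 700 N single-support plateau, 600/650 N heel/toe peaks, a full
    heel→toe CoP sweep, 5 N sensor noise during stance and rare
    sub-floor blips while the foot is airborne.
    """

    mean_stride_time: float = 1.1   # s
    stride_time_cv: float = 4.0     # % of the mean
    swing_fraction: float = 0.38    # airborne share of the stride
    swing_fraction_cv: float = 4.0  # % of the fraction
    body_force: float = 700.0       # N, mid-stance plateau of the summed VGRF
    heel_peak: float = 600.0        # N, summed heel-sensor peak at heel strike
    toe_peak: float = 650.0         # N, summed toe-sensor peak at toe off
    cop_y_excursion: float = 0.9    # modulation depth of the heel→toe sweep, 0..1
    sensor_noise_sd: float = 5.0    # N, additive Gaussian noise during stance
    swing_blip_rate: float = 1.0    # spurious readouts per second of swing
    swing_blip_max: float = 15.0    # N, strictly below the 20 N noise floor

    def __post_init__(self) -> None:
        if not 0 < self.swing_fraction < 1:
            raise ValueError("swing_fraction must lie in (0, 1)")
        if min(self.body_force, self.heel_peak, self.toe_peak) < 0:
            raise ValueError("forces must be nonnegative")
        if self.swing_blip_max >= 20.0:
            raise ValueError("swing blips must stay below the 20 N noise floor")
        if min(self.stride_time_cv, self.swing_fraction_cv) < 0:
            raise ValueError("CVs must be nonnegative")
        if not 0 <= self.cop_y_excursion <= 1:
            raise ValueError("cop_y_excursion must lie in [0, 1]")


def pd_profile(control: GaitProfile | None = None) -> GaitProfile:
    """Default PD contrast: timing CVs ×2, peak forces ×0.85, CoP sweep ×0.6."""
    control = control or GaitProfile()
    return replace(control,
                   stride_time_cv=control.stride_time_cv * 2.0,
                   swing_fraction_cv=control.swing_fraction_cv * 2.0,
                   heel_peak=control.heel_peak * 0.85,
                   toe_peak=control.toe_peak * 0.85,
                   cop_y_excursion=control.cop_y_excursion * 0.6)


@dataclass
class CohortConfig:
    """Shape of a simulated cohort (defaults emulate a 29 PD / 18 control study)."""

    n_control: int = 18
    n_pd: int = 29
    control_profile: GaitProfile = field(default_factory=GaitProfile)
    pd_profile: GaitProfile = field(default_factory=pd_profile)
    duration: float = 140.0        # s: 20 s initiation trim + 120 s analysed
    sampling_rate: float = 100.0   # Hz
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_pd < 1:
            raise ValueError("need at least one subject per group")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")


@dataclass
class StrideTruth:
    """Ground truth of one programmed stride (0-based trimmed-free indices)."""

    stance_start: int
    stance_len: int
    swing_len: int
    stride_time: float  # s, realized
    swing_time: float   # s, realized

    @property
    def end(self) -> int:
        return self.stance_start + self.stance_len + self.swing_len


@dataclass
class GroundTruth:
    """Everything the generator knows about one simulated subject."""

    subject_id: str
    group: str
    seed: int
    profile: GaitProfile
    cycles: list[StrideTruth]
    heel_peak_programmed: float
    toe_peak_programmed: float
    cop_y: np.ndarray  # (n,) realized left-foot CoP y; NaN off stance

    def to_json_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "seed": int(self.seed),
            "profile": asdict(self.profile),
            "heel_peak_programmed": self.heel_peak_programmed,
            "toe_peak_programmed": self.toe_peak_programmed,
            "cycles": [asdict(c) for c in self.cycles],
        }


def _heel_shape(m: int) -> np.ndarray:
    """Unit-peak heel activation: quarter-sine rise, raised-cosine decay."""
    r = RISE_SAMPLES
    d = max(int(round(0.35 * m)) - r, 2)
    shape = np.zeros(m)
    t = np.arange(r + 1)
    shape[: r + 1] = np.sin(np.pi * (t + 1) / (2 * (r + 1)))
    u = np.arange(1, d + 1)
    stop = min(r + 1 + d, m)
    shape[r + 1: stop] = np.cos(np.pi * u[: stop - r - 1] / (2 * d))
    return shape


def _stance_frames(rng: np.random.Generator, profile: GaitProfile, m: int,
                   heel_cols: np.ndarray, mid_cols: np.ndarray, toe_cols: np.ndarray,
                   mid_y: np.ndarray) -> np.ndarray:
    """(m, 8) noiseless per-sensor forces for one stance of m samples."""
    if m < RISE_SAMPLES + 4:
        raise ValueError(f"infeasible profile: stance of {m} samples is shorter "
                         f"than the heel/toe activation windows")
    frames = np.zeros((m, 8))
    heel = _heel_shape(m)
    toe = heel[::-1]
    frames[:, heel_cols] = (profile.heel_peak / len(heel_cols)) * heel[:, None]
    frames[:, toe_cols] = (profile.toe_peak / len(toe_cols)) * toe[:, None]

    plateau = profile.body_force * tukey(m, alpha=0.4)
    # heel→toe sweep of the midfoot weights: sensors low on the foot carry
    # more load early in stance, high sensors late; depth = cop_y_excursion
    y_hat = mid_y - mid_y.mean()
    denom = np.abs(y_hat).max()
    y_hat = y_hat / denom if denom > 0 else y_hat
    ramp = np.linspace(-1.0, 1.0, m)
    weights = 1.0 + profile.cop_y_excursion * ramp[:, None] * y_hat[None, :]
    np.clip(weights, 0.0, None, out=weights)
    weights /= weights.sum(axis=1, keepdims=True)
    frames[:, mid_cols] = plateau[:, None] * weights
    return frames


def _simulate_foot(rng: np.random.Generator, profile: GaitProfile, n: int,
                   sampling_rate: float, heel_cols, mid_cols, toe_cols,
                   mid_y) -> tuple[np.ndarray, list[StrideTruth]]:
    fs = sampling_rate
    forces = np.zeros((n, 8))
    cycles: list[StrideTruth] = []
    cursor = int(round(0.3 * fs))  # brief airborne lead-in before the first strike
    lo, hi = STRIDE_TRUNCATION
    while True:
        stride_time = rng.normal(profile.mean_stride_time,
                                 profile.stride_time_cv / 100.0 * profile.mean_stride_time)
        stride_time = float(np.clip(stride_time, lo, hi))
        swing_frac = rng.normal(profile.swing_fraction,
                                profile.swing_fraction_cv / 100.0 * profile.swing_fraction)
        swing_frac = float(np.clip(swing_frac, 0.15, 0.60))
        stride_len = int(round(stride_time * fs))
        stance_len = int(round((1.0 - swing_frac) * stride_len))
        swing_len = stride_len - stance_len
        if cursor + stride_len > n:
            break
        frames = _stance_frames(rng, profile, stance_len,
                                heel_cols, mid_cols, toe_cols, mid_y)
        if profile.sensor_noise_sd > 0:
            frames = frames + rng.normal(0.0, profile.sensor_noise_sd, frames.shape)
            np.clip(frames, 0.0, None, out=frames)
        forces[cursor:cursor + stance_len] = frames
        cycles.append(StrideTruth(stance_start=cursor, stance_len=stance_len,
                                  swing_len=swing_len,
                                  stride_time=stride_len / fs,
                                  swing_time=swing_len / fs))
        cursor += stride_len
    # spurious sub-floor sensor readouts while the foot is airborne
    if profile.swing_blip_rate > 0 and profile.swing_blip_max > 0:
        airborne = forces.sum(axis=1) == 0
        idx = np.flatnonzero(airborne)
        hit = idx[rng.random(len(idx)) < profile.swing_blip_rate / fs]
        if len(hit):
            sensors = rng.integers(0, 8, size=len(hit))
            forces[hit, sensors] = rng.uniform(0.0, profile.swing_blip_max, size=len(hit))
    return forces, cycles


def simulate_subject(profile: GaitProfile, layout: SensorLayout | None = None,
                     duration: float = 140.0, sampling_rate: float = 100.0,
                     seed: int = 0, subject_id: str = "sim", group: str = "control",
                     ) -> tuple[VGRFRecord, GroundTruth]:
    """Simulate one subject-walk; both feet in near anti-phase.

    Deterministic given the seed: the same call yields a bit-identical
    record and ground truth.  The per-foot totals equal the sensor sums
    by construction.
    """
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))

    cols = {}
    for foot in ("left", "right"):
        cols[foot] = (layout.role_columns(foot, "heel"),
                      layout.role_columns(foot, "midfoot"),
                      layout.role_columns(foot, "toe"))
    mid_y = {foot: layout.coordinates(foot, "y")[cols[foot][1]] for foot in cols}

    left, cycles = _simulate_foot(rng, profile, n, sampling_rate,
                                  *cols["left"], mid_y["left"])
    right, _ = _simulate_foot(rng, profile, n, sampling_rate,
                              *cols["right"], mid_y["right"])
    # offset the contralateral foot by half a mean stride (anti-phase)
    right = np.roll(right, int(round(0.5 * profile.mean_stride_time * sampling_rate)),
                    axis=0)

    time = np.arange(n) / sampling_rate
    record = VGRFRecord(subject_id=subject_id, group=group,
                        sampling_rate=sampling_rate, time=time,
                        left_forces=left, right_forces=right,
                        left_total=left.sum(axis=1), right_total=right.sum(axis=1))
    record.validate()

    totals = left.sum(axis=1)
    y_coords = layout.coordinates("left", "y")
    with np.errstate(invalid="ignore", divide="ignore"):
        cop_y = np.where(totals > 0, left @ y_coords / np.where(totals > 0, totals, 1.0),
                         np.nan)
    truth = GroundTruth(subject_id=subject_id, group=group, seed=seed,
                        profile=profile, cycles=cycles,
                        heel_peak_programmed=profile.heel_peak,
                        toe_peak_programmed=profile.toe_peak, cop_y=cop_y)
    return record, truth


@dataclass
class SimulatedCohort:
    config: CohortConfig
    records: list[VGRFRecord]
    ground_truths: list[GroundTruth]

    @property
    def labels(self) -> list[str]:
        return [r.group for r in self.records]


def child_seed(rng_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed, recorded in the ground truth."""
    ss = np.random.SeedSequence([int(rng_seed), int(subject_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_cohort(config: CohortConfig,
                    layout: SensorLayout | None = None) -> SimulatedCohort:
    """Simulate a labeled cohort; per-subject seeds derive from ``rng_seed``."""
    layout = layout or default_layout()
    records, truths = [], []
    plan = ([("control", config.control_profile)] * config.n_control
            + [("pd", config.pd_profile)] * config.n_pd)
    for idx, (group, profile) in enumerate(plan):
        seed = child_seed(config.rng_seed, idx)
        sid = f"{group}_{idx:03d}"
        rec, truth = simulate_subject(profile, layout=layout,
                                      duration=config.duration,
                                      sampling_rate=config.sampling_rate,
                                      seed=seed, subject_id=sid, group=group)
        records.append(rec)
        truths.append(truth)
    return SimulatedCohort(config=config, records=records, ground_truths=truths)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Write records (19-column dialect), per-subject ground-truth JSON and
    a CSV manifest into ``out_dir``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec, truth in zip(cohort.records, cohort.ground_truths):
        rec_path = out_dir / f"{rec.subject_id}.txt"
        write_record(rec, rec_path)
        with open(out_dir / f"{rec.subject_id}.truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1)
        entries.append(ManifestEntry(path=rec_path.name, subject_id=rec.subject_id,
                                     group=rec.group))
    manifest = CohortManifest(entries)
    return write_manifest(manifest, out_dir / "manifest.csv")
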