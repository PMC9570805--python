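"""Synthetic multi-sensor cohort generator.

No public dataset of the laboratory recordings exists, so the pipeline is
exercised on synthetic cohorts of virtual participants.  Each participant
"performs" every one of the eight shoulder-loading activities once, in a
randomized order with randomized per-block durations; per-site inertial
channels are composed from a class-specific signature (gravity along a
posture-dependent direction, a modulated movement component, the wheel
rotation profile, additive Gaussian noise) and the two EMG channels are a
band-limited stochastic carrier amplitude-modulated by the class's muscle
activation envelope.  Inter-participant variability enters through
multiplicative amplitude scales, a cycle-frequency scale, phase offsets and
a posture jitter, loosely emulating how different people execute the same
instructed activity differently.

Everything is driven by a single integer seed through numpy SeedSequence
spawning, so a cohort regenerates bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .activities import (
    ActivityClass, ActivitySignature, SensorSite, SiteMotion,
    EMG_CHANNELS, EMG_RATE_HZ, GRAVITY, IMU_RATE_HZ, SIGNATURES, SITES,
)

# durations snap to this grid so IMU (100 Hz) and EMG (1000 Hz) block
# lengths stay integer and mutually aligned
_DURATION_GRID_S = 0.1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScheduleConfig:
    """Bounds for the per-activity block durations (seconds)."""

    min_duration: float = 8.0
    max_duration: float = 12.0
    blocks_per_class: int = 1

    def validate(self) -> None:
        if self.min_duration <= 0 or self.max_duration <= 0:
            raise ValueError("schedule durations must be positive")
        if self.min_duration > self.max_duration:
            raise ValueError("schedule min_duration exceeds max_duration")
        if self.blocks_per_class < 1:
            raise ValueError("blocks_per_class must be >= 1")


@dataclass
class NoiseConfig:
    """Additive sensor noise levels; `scale` is the difficulty knob."""

    accel_sd: float = 0.25   # m/s^2
    gyro_sd: float = 2.0     # deg/s
    emg_base: float = 0.03   # baseline activation (fraction of reference)
    scale: float = 1.0       # multiplies all noise SDs

    @property
    def accel(self) -> float:
        return self.accel_sd * self.scale

    @property
    def gyro(self) -> float:
        return self.gyro_sd * self.scale


@dataclass
class VariabilityConfig:
    """Spread of the per-participant execution-style parameters."""

    amp_sigma: float = 0.15          # log-normal sigma of amplitude scales
    freq_jitter: float = 0.10        # cycle frequency in [1-j, 1+j]
    posture_jitter_deg: float = 5.0  # SD of the per-participant pitch offset
    emg_ref_sigma: float = 0.2       # log-normal sigma of posture references


@dataclass
class CohortConfig:
    n_participants: int = 10
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    variability: VariabilityConfig = field(default_factory=VariabilityConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key, sub in (("schedule", ScheduleConfig),
                         ("noise", NoiseConfig),
                         ("variability", VariabilityConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantProfile:
    """Execution style of one virtual participant."""

    participant_id: str
    amp_scale: dict          # modality ("accel"|"gyro"|"emg") -> factor > 0
    freq_scale: float        # > 0, scales all cyclic frequencies
    phase_offset: float      # radians
    posture_offset: float    # radians, added to every posture pitch
    emg_posture_refs: tuple  # (biceps, deltoid) reference envelope levels

    def __post_init__(self):
        if any(v <= 0 for v in self.amp_scale.values()):
            raise ValueError("amp_scale factors must be strictly positive")
        if self.freq_scale <= 0:
            raise ValueError("freq_scale must be strictly positive")
        if any(r <= 0 for r in self.emg_posture_refs):
            raise ValueError("emg_posture_refs must be strictly positive")


@dataclass(frozen=True)
class ActivitySchedule:
    """Ordered (activity, duration-in-seconds) blocks for one session."""

    blocks: tuple  # tuple of (ActivityClass, float)

    def __post_init__(self):
        present = {a for a, _ in self.blocks}
        if present != set(ActivityClass):
            missing = sorted(c.code for c in set(ActivityClass) - present)
            raise ValueError(f"schedule misses activity classes: {missing}")
        if any(d <= 0 for _, d in self.blocks):
            raise ValueError("block durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.blocks))


@dataclass
class SiteChannels:
    accel: np.ndarray  # (n, 3) m/s^2 at 100 Hz
    gyro: np.ndarray   # (n, 3) deg/s at 100 Hz


@dataclass
class RawRecording:
    """Native-rate recording: 100 Hz IMU per site, 1000 Hz EMG on the UA."""

    sites: dict            # SensorSite -> SiteChannels
    emg: np.ndarray        # (10*n, 2) mV-scale, channels (biceps, deltoid)

    def __post_init__(self):
        n = self.n_imu_samples
        for site, ch in self.sites.items():
            if ch.accel.shape != (n, 3) or ch.gyro.shape != (n, 3):
                raise ValueError(f"inconsistent channel lengths at {site.code}")
        if self.emg.shape != (10 * n, len(EMG_CHANNELS)):
            raise ValueError(
                f"EMG must hold {10 * n} x {len(EMG_CHANNELS)} samples "
                f"(1000 Hz vs 100 Hz IMU), got {self.emg.shape}")

    @property
    def n_imu_samples(self) -> int:
        return next(iter(self.sites.values())).accel.shape[0]

    @property
    def duration(self) -> float:
        return self.n_imu_samples / IMU_RATE_HZ


@dataclass(frozen=True)
class AnnotationTrack:
    """Contiguous, non-overlapping labeled intervals covering a recording."""

    intervals: tuple  # tuple of (start_s, end_s, ActivityClass)

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("annotation track is empty")
        if abs(self.intervals[0][0]) > 1e-9:
            raise ValueError("first interval must start at 0 s")
        for (s0, e0, _), (s1, _, _) in zip(self.intervals, self.intervals[1:]):
            if e0 <= s0:
                raise ValueError("interval with nonpositive duration")
            if abs(s1 - e0) > 1e-9:
                raise ValueError("annotation intervals must be contiguous")
        s, e, _ = self.intervals[-1]
        if e <= s:
            raise ValueError("interval with nonpositive duration")

    @property
    def duration(self) -> float:
        return float(self.intervals[-1][1])


@dataclass
class Dataset:
    """A generated cohort: one (profile, recording, annotation) per person."""

    participants: list   # list of (ParticipantProfile, RawRecording, AnnotationTrack)
    cohort_seed: int
    config: CohortConfig

    def __post_init__(self):
        ids = [p.participant_id for p, _, _ in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant_ids must be unique")

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def participant_ids(self) -> list:
        return [p.participant_id for p, _, _ in self.participants]


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def make_schedule(config: ScheduleConfig, rng: np.random.Generator) -> ActivitySchedule:
    """Randomized activity order with durations drawn from the bounds.

    Durations are quantized to 0.1 s so that every block holds an integer
    number of both IMU and EMG samples.
    """
    config.validate()
    classes = list(ActivityClass) * config.blocks_per_class
    order = rng.permutation(len(classes))
    blocks = []
    for idx in order:
        d = rng.uniform(config.min_duration, config.max_duration)
        d = max(_DURATION_GRID_S, round(d / _DURATION_GRID_S) * _DURATION_GRID_S)
        blocks.append((classes[idx], float(d)))
    return ActivitySchedule(blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# waveform helpers
# ---------------------------------------------------------------------------

def _smooth_gate(t: np.ndarray, period: float, duty: float, edge: float = 0.4) -> np.ndarray:
    """Periodic on/off envelope in [0, 1] with raised-cosine edges."""
    phase = np.mod(t, period)
    on = duty * period
    gate = np.zeros_like(t)
    rise = np.clip(phase / edge, 0.0, 1.0)
    fall = np.clip((on - phase) / edge, 0.0, 1.0)
    gate = np.minimum(rise, fall)
    gate = np.clip(gate, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * gate)


def _hash_wave(n: int, rng: np.random.Generator, cutoff_hz: float = 2.0) -> np.ndarray:
    """Low-pass-filtered unit-variance noise: aimless fidgeting movement."""
    raw = rng.standard_normal(n + 400)
    sos = signal.butter(2, cutoff_hz, btype="low", fs=IMU_RATE_HZ, output="sos")
    sm = signal.sosfilt(sos, raw)[400:]
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _modulation(sig: ActivitySignature, profile: ParticipantProfile,
                t: np.ndarray, rng: np.random.Generator):
    """Return (movement waveform, activation envelope in [0, 1])."""
    freq = sig.arm_cycle_freq * profile.freq_scale
    phase = profile.phase_offset + rng.uniform(0, 2 * np.pi)
    if sig.modulation == "cycle":
        wave = np.sin(2 * np.pi * freq * t + phase)
        env = np.abs(wave)
    elif sig.modulation == "bouts":
        period = sig.bout_period * rng.uniform(0.85, 1.15)
        gate = _smooth_gate(t, period, sig.bout_duty)
        wave = gate * np.sin(2 * np.pi * freq * t + phase)
        env = gate
    elif sig.modulation == "hash":
        wave = _hash_wave(t.size, rng)
        env = np.abs(wave)
        env = env / max(env.max(), 1e-12)
    else:  # pragma: no cover - signatures are package-defined
        raise ValueError(f"unknown modulation {sig.modulation!r}")
    return wave, env


def _wheel_profile(sig: ActivitySignature, profile: ParticipantProfile,
                   t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Wheel angular velocity (deg/s) about the wheel axis."""
    if not sig.wheel_moves:
        return np.zeros_like(t)
    omega = sig.wheel_omega * profile.amp_scale["gyro"]
    if sig.wheel_mode == "continuous":
        freq = sig.arm_cycle_freq * profile.freq_scale
        ripple = sig.wheel_ripple * np.sin(
            2 * np.pi * freq * t + profile.phase_offset)
        w = omega + ripple
        # spin-up / spin-down ramps: the wheel starts from and returns to
        # standstill inside the block, which is what makes block boundaries
        # recognizable in the wheel gyroscope
        ramp = np.clip(t / 1.0, 0, 1) * np.clip((t[-1] - t) / 1.0, 0, 1)
        return w * ramp
    # bouts: a few push episodes separated by standstill, ending at zero
    period = sig.bout_period * rng.uniform(0.9, 1.1)
    gate = _smooth_gate(t, period, sig.bout_duty, edge=0.6)
    # occasional backward pushes flip the rotation sign per bout
    bout_idx = np.floor(t / period).astype(int)
    signs = rng.choice([-1.0, 1.0], size=bout_idx.max() + 1, p=[0.25, 0.75])
    w = omega * gate * signs[bout_idx]
    # the wheel is at standstill over the final second of the block
    # ("ends when wheel stops rotating"), with a smooth spin-down before
    w *= np.clip(((t[-1] - 1.0) - t) / 0.8, 0, 1)
    return w


def _axis_vectors(site: SensorSite):
    """Fixed per-site unit vectors for the movement components.

    The dominant movement direction at a site is anatomy-driven, not
    activity-driven, so all classes share a site's axes; classes must be
    told apart by waveform, amplitude, posture and the wheel profile.
    """
    k = int(site)
    golden = 2.399963229728653  # golden angle, radians
    a1, a2 = golden * (k + 1), golden * (k + 1) * 1.7
    u_acc = np.array([np.cos(a1), np.sin(a1), np.sin(a1 * 0.5)])
    u_gyr = np.array([np.sin(a2), np.cos(a2), np.cos(a2 * 0.5)])
    return u_acc / np.linalg.norm(u_acc), u_gyr / np.linalg.norm(u_gyr)


def _gravity_vector(pitch: float) -> np.ndarray:
    return GRAVITY * np.array([np.sin(pitch), 0.0, np.cos(pitch)])


# ---------------------------------------------------------------------------
# per-activity synthesis
# ---------------------------------------------------------------------------

def synth_activity(activity: ActivityClass, profile: ParticipantProfile,
                   duration: float, rng: np.random.Generator,
                   noise: NoiseConfig | None = None) -> dict:
    """Synthesize one activity block at native rates.

    Returns ``{"sites": {SensorSite: SiteChannels}, "emg": (10n, 2) array}``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not isinstance(activity, ActivityClass):
        activity = ActivityClass(activity)
    noise = noise or NoiseConfig()
    sig = SIGNATURES[activity]

    n = int(round(duration * IMU_RATE_HZ))
    t = np.arange(n) / IMU_RATE_HZ
    wave, env = _modulation(sig, profile, t, rng)
    wheel = _wheel_profile(sig, profile, t, rng)

    sites = {}
    for site in SITES:
        motion = sig.site_motion.get(site, SiteMotion())
        u_acc, u_gyr = _axis_vectors(site)
        pitch = sig.posture_pitch.get(site, 0.0)
        if site in (SensorSite.UA, SensorSite.FA, SensorSite.THOR):
            pitch += profile.posture_offset
        acc = (_gravity_vector(pitch)[None, :]
               + motion.accel_amp * profile.amp_scale["accel"]
               * wave[:, None] * u_acc[None, :])
        gyr = (motion.gyro_amp * profile.amp_scale["gyro"]
               * wave[:, None] * u_gyr[None, :])
        if site is SensorSite.WCW:
            gyr = gyr.copy()
            gyr[:, 2] += wheel
        acc = acc + rng.normal(0.0, noise.accel, (n, 3))
        gyr = gyr + rng.normal(0.0, noise.gyro, (n, 3))
        sites[site] = SiteChannels(accel=acc, gyro=gyr)

    emg = _synth_emg(sig, profile, env, rng, noise)
    return {"sites": sites, "emg": emg}


def _emg_carrier(n: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited (20-450 Hz) noise carrier with unit rectified mean."""
    raw = rng.standard_normal(n + 2000)
    sos = signal.butter(4, [20.0, 450.0], btype="band",
                        fs=EMG_RATE_HZ, output="sos")
    x = signal.sosfilt(sos, raw)[2000:]
    return x / max(np.mean(np.abs(x)), 1e-12)


def _synth_emg(sig: ActivitySignature, profile: ParticipantProfile,
               env100: np.ndarray, rng: np.random.Generator,
               noise: NoiseConfig) -> np.ndarray:
    """Raw EMG: carrier x (baseline + class burst level x activation)."""
    n_emg = env100.size * 10
    env = np.repeat(env100, 10)
    out = np.empty((n_emg, len(EMG_CHANNELS)))
    for m, level in enumerate(sig.emg_burst_level):
        carrier = _emg_carrier(n_emg, rng)
        amp = (profile.emg_posture_refs[m] * profile.amp_scale["emg"]
               * (noise.emg_base * noise.scale + level * env))
        out[:, m] = amp * carrier
    return out


def synth_posture_hold(profile: ParticipantProfile, duration: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Raw EMG of the two static normalization postures (constant level).

    The rectified-smoothed envelope of this signal recovers the
    participant's ``emg_posture_refs`` (up to carrier statistics), which is
    what makes reference-based normalization meaningful.
    """
    n_emg = int(round(duration * EMG_RATE_HZ))
    out = np.empty((n_emg, len(EMG_CHANNELS)))
    for m in range(len(EMG_CHANNELS)):
        carrier = _emg_carrier(n_emg, rng)
        out[:, m] = profile.emg_posture_refs[m] * carrier
    return out


def static_posture_reference(profile: ParticipantProfile) -> tuple:
    """Reference envelope levels (biceps, deltoid) for EMG normalization."""
    return tuple(profile.emg_posture_refs)


# ---------------------------------------------------------------------------
# participant / cohort assembly
# ---------------------------------------------------------------------------

def generate_participant(profile: ParticipantProfile, schedule: ActivitySchedule,
                         rng: np.random.Generator,
                         noise: NoiseConfig | None = None):
    """Concatenate activity blocks into one recording plus its annotation."""
    noise = noise or NoiseConfig()
    acc = {s: [] for s in SITES}
    gyr = {s: [] for s in SITES}
    emg = []
    intervals = []
    t0 = 0.0
    for activity, dur in schedule.blocks:
        block = synth_activity(activity, profile, dur, rng, noise)
        for s in SITES:
            acc[s].append(block["sites"][s].accel)
            gyr[s].append(block["sites"][s].gyro)
        emg.append(block["emg"])
        n_block = block["sites"][SITES[0]].accel.shape[0]
        t1 = t0 + n_block / IMU_RATE_HZ
        intervals.append((t0, t1, activity))
        t0 = t1
    sites = {s: SiteChannels(accel=np.concatenate(acc[s]),
                             gyro=np.concatenate(gyr[s])) for s in SITES}
    recording = RawRecording(sites=sites, emg=np.concatenate(emg))
    return recording, AnnotationTrack(intervals=tuple(intervals))


def _draw_profile(pid: str, var: VariabilityConfig,
                  rng: np.random.Generator) -> ParticipantProfile:
    amp = {m: float(rng.lognormal(0.0, var.amp_sigma))
           for m in ("accel", "gyro", "emg")}
    return ParticipantProfile(
        participant_id=pid,
        amp_scale=amp,
        freq_scale=float(rng.uniform(1 - var.freq_jitter, 1 + var.freq_jitter)),
        phase_offset=float(rng.uniform(0, 2 * np.pi)),
        posture_offset=float(rng.normal(0, np.deg2rad(var.posture_jitter_deg))),
        emg_posture_refs=(float(rng.lognormal(0.0, var.emg_ref_sigma)),
                          float(rng.lognormal(0.0, var.emg_ref_sigma))),
    )


def generate_cohort(n_participants: int = 10,
                    config: CohortConfig | None = None,
                    seed: int = 0) -> Dataset:
    """Generate a full cohort; bit-identical for identical (seed, config)."""
    if n_participants < 2:
        raise ValueError("need at least 2 participants for leave-one-subject-out")
    config = config or CohortConfig()
    config.schedule.validate()
    children = np.random.SeedSequence(seed).spawn(n_participants)
    participants = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i + 1:02d}"
        profile = _draw_profile(pid, config.variability, rng)
        schedule = make_schedule(config.schedule, rng)
        recording, track = generate_participant(profile, schedule, rng,
                                                config.noise)
        participants.append((profile, recording, track))
    return Dataset(participants=participants, cohort_seed=seed, config=config)


# ---------------------------------------------------------------------------
# on-disk layout: one directory per participant, per-site CSV
# ---------------------------------------------------------------------------

def write_cohort(dataset: Dataset, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"cohort_seed": dataset.cohort_seed,
            "config": dataset.config.to_dict(),
            "participants": dataset.participant_ids}
    (out_dir / "cohort.json").write_text(json.dumps(meta, indent=2))
    for profile, rec, track in dataset.participants:
        pdir = out_dir / profile.participant_id
        pdir.mkdir(exist_ok=True)
        n = rec.n_imu_samples
        t = np.arange(n) / IMU_RATE_HZ
        for site, ch in rec.sites.items():
            cols = {"time_s": t}
            for j, ax in enumerate("xyz"):
                cols[f"{site.code}_acc_{ax}"] = ch.accel[:, j]
            for j, ax in enumerate("xyz"):
                cols[f"{site.code}_gyr_{ax}"] = ch.gyro[:, j]
            pd.DataFrame(cols).to_csv(pdir / f"{site.code}.csv",
                                      index=False, float_format="%.6g")
        t_emg = np.arange(rec.emg.shape[0]) / EMG_RATE_HZ
        emg_cols = {"time_s": t_emg}
        for m, name in enumerate(EMG_CHANNELS):
            emg_cols[f"UA_emg_{name}"] = rec.emg[:, m]
        pd.DataFrame(emg_cols).to_csv(pdir / "UA_emg.csv",
                                      index=False, float_format="%.6g")
        ann = pd.DataFrame(
            [(s, e, a.code) for s, e, a in track.intervals],
            columns=["start_s", "end_s", "class"])
        ann.to_csv(pdir / "annotation.csv", index=False)
        prof = asdict(profile)
        (pdir / "profile.json").write_text(json.dumps(prof, indent=2))


def read_cohort(in_dir) -> Dataset:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "cohort.json").read_text())
    config = CohortConfig.from_dict(meta["config"])
    participants = []
    for pid in meta["participants"]:
        pdir = in_dir / pid
        prof_d = json.loads((pdir / "profile.json").read_text())
        prof_d["emg_posture_refs"] = tuple(prof_d["emg_posture_refs"])
        profile = ParticipantProfile(**prof_d)
        sites = {}
        for site in SITES:
            df = pd.read_csv(pdir / f"{site.code}.csv")
            acc = df[[f"{site.code}_acc_{ax}" for ax in "xyz"]].to_numpy()
            gyr = df[[f"{site.code}_gyr_{ax}" for ax in "xyz"]].to_numpy()
            sites[site] = SiteChannels(accel=acc, gyro=gyr)
        emg_df = pd.read_csv(pdir / "UA_emg.csv")
        emg = emg_df[[f"UA_emg_{n}" for n in EMG_CHANNELS]].to_numpy()
        rec = RawRecording(sites=sites, emg=emg)
        ann = pd.read_csv(pdir / "annotation.csv")
        track = AnnotationTrack(intervals=tuple(
            (float(r.start_s), float(r.end_s), ActivityClass.from_code(r["class"]))
            for _, r in ann.iterrows()))
        participants.append((profile, rec, track))
    return Dataset(participants=participants, cohort_seed=meta["cohort_seed"],
                   config=config)
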