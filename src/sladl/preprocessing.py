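"""Raw recordings -> 10 Hz feature sequences with per-sample labels.

The classifier consumes a T x D matrix at 10 Hz.  IMU channels (100 Hz) are
reduced by a non-overlapping block mean of 10 samples; EMG channels
(1000 Hz) go through the envelope chain -- zero-phase 4th-order Butterworth
high-pass at 20 Hz, offset correction, rectification, zero-phase 4th-order
Butterworth low-pass at 2 Hz -- and are then decimated to 10 Hz.  The
envelope is band-limited far below the 5 Hz post-decimation Nyquist, so
plain sample picking is a sufficient decimator.  Features are kept in their
native mixed units: no normalization, centering or scaling is applied to
the model input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import signal

from .activities import (
    ActivityClass, SensorSite, EMG_CHANNELS, EMG_RATE_HZ, SITES,
    TARGET_RATE_HZ,
)
from .cohort import AnnotationTrack, RawRecording


@dataclass
class EnvelopeConfig:
    """EMG envelope extraction parameters."""

    hp_cutoff: float = 20.0      # Hz, high-pass before rectification
    lp_cutoff: float = 2.0       # Hz, low-pass after rectification
    filter_order: int = 4
    bidirectional: bool = True   # forward-backward (zero-phase) filtering
    emg_rate: float = EMG_RATE_HZ
    target_rate: float = TARGET_RATE_HZ

    def validate(self) -> None:
        nyq = self.emg_rate / 2
        if not (0 < self.hp_cutoff < nyq and 0 < self.lp_cutoff < nyq):
            raise ValueError("cutoffs must lie inside (0, Nyquist)")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    @property
    def decimation(self) -> int:
        return int(round(self.emg_rate / self.target_rate))

    @property
    def min_samples(self) -> int:
        # generous warm-up requirement: three filter "memory lengths" of the
        # slowest stage
        return int(3 * self.filter_order * self.emg_rate / self.lp_cutoff)


class SensorCombination(Enum):
    """The four channel subsets used in the sensor-reduction ablation."""

    C1 = 1   # all five IMUs (accel + gyro) + 2 EMG -> 32 channels
    C2 = 2   # all five IMUs, no EMG               -> 30 channels
    C3 = 3   # upper-arm IMU only                  ->  6 channels
    C4 = 4   # forearm IMU only                    ->  6 channels

    @property
    def sites(self) -> tuple:
        if self in (SensorCombination.C1, SensorCombination.C2):
            return SITES
        if self is SensorCombination.C3:
            return (SensorSite.UA,)
        return (SensorSite.FA,)

    @property
    def with_emg(self) -> bool:
        return self is SensorCombination.C1

    @property
    def channel_names(self) -> list:
        names = []
        for site in self.sites:
            for mod in ("acc", "gyr"):
                for ax in "xyz":
                    names.append(f"{site.code}_{mod}_{ax}")
        if self.with_emg:
            names += [f"UA_emg_{m}" for m in EMG_CHANNELS]
        return names

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


@dataclass
class FeatureSequence:
    """10 Hz feature matrix with aligned per-sample activity labels."""

    X: np.ndarray            # (T, D), mixed units, unnormalized
    y: np.ndarray            # (T,) int labels in 0..7
    participant_id: str
    combination: SensorCombination
    channel_names: list = field(default_factory=list)

    def __post_init__(self):
        if self.X.ndim != 2 or self.y.ndim != 1:
            raise ValueError("X must be (T, D), y must be (T,)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("feature matrix and label vector lengths differ")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= len(ActivityClass)):
            raise ValueError("labels outside the 8 activity classes")

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]


# ---------------------------------------------------------------------------
# channel-level operations
# ---------------------------------------------------------------------------

def downsample_imu(x: np.ndarray, factor: int = 10) -> np.ndarray:
    """100 Hz -> 10 Hz by non-overlapping block averaging.

    ``out[k] = mean(x[factor*k : factor*(k+1)])``; a trailing partial block
    is dropped.  Works on (n,) or (n, C) arrays along axis 0.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] == 0:
        raise ValueError("cannot downsample an empty signal")
    if x.shape[0] < factor:
        raise ValueError(f"need at least {factor} samples, got {x.shape[0]}")
    n_out = x.shape[0] // factor
    trimmed = x[:n_out * factor]
    shape = (n_out, factor) + trimmed.shape[1:]
    return trimmed.reshape(shape).mean(axis=1)


def emg_envelope(x: np.ndarray, cfg: EnvelopeConfig | None = None) -> np.ndarray:
    """Smooth rectified EMG envelope, downsampled to the target rate.

    Chain (in order): zero-phase Butterworth high-pass -> mean subtraction
    -> rectification -> zero-phase Butterworth low-pass -> decimation.
    Filter ringing can push the low-passed rectified signal slightly below
    zero; those samples are clamped to 0.
    """
    cfg = cfg or EnvelopeConfig()
    cfg.validate()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emg_envelope expects a single channel")
    if x.size < cfg.min_samples:
        raise ValueError(
            f"EMG too short for envelope extraction: need >= {cfg.min_samples}"
            f" samples at {cfg.emg_rate:g} Hz, got {x.size}")
    sos_hp = signal.butter(cfg.filter_order, cfg.hp_cutoff, btype="high",
                           fs=cfg.emg_rate, output="sos")
    sos_lp = signal.butter(cfg.filter_order, cfg.lp_cutoff, btype="low",
                           fs=cfg.emg_rate, output="sos")

    def filt(sos, sig_in, cutoff):
        if not cfg.bidirectional:
            return signal.sosfilt(sos, sig_in)
        # pad far enough to cover the filter transient; scipy's default pad
        # is much shorter than a 2 Hz transient at 1 kHz, which would break
        # the zero-phase (time-reversal) symmetry near the edges
        padlen = min(sig_in.size - 1, int(6 * cfg.emg_rate / cutoff))
        return signal.sosfiltfilt(sos, sig_in, padlen=padlen)

    hp = filt(sos_hp, x, cfg.hp_cutoff)
    hp = hp - hp.mean()          # offset correction
    rect = np.abs(hp)            # rectification
    env = filt(sos_lp, rect, cfg.lp_cutoff)
    env = np.maximum(env, 0.0)
    return env[::cfg.decimation]


def normalize_emg(env: np.ndarray, ref: float) -> np.ndarray:
    """Express an envelope relative to a static-posture reference level."""
    if ref <= 0:
        raise ValueError("EMG reference level must be strictly positive")
    return np.asarray(env, dtype=float) / ref


def labels_at_10hz(track: AnnotationTrack, T: int,
                   rate: float = TARGET_RATE_HZ) -> np.ndarray:
    """Per-sample labels: sample k (time k/rate) takes the class of its
    containing interval, intervals being half-open [start, end)."""
    if T < 0:
        raise ValueError("T must be nonnegative")
    needed = T / rate
    if track.duration < needed - 1e-9:
        raise ValueError(
            f"annotation covers {track.duration:g} s but {needed:g} s needed")
    starts = np.array([s for s, _, _ in track.intervals])
    classes = np.array([int(a) for _, _, a in track.intervals])
    times = np.arange(T) / rate
    idx = np.searchsorted(starts, times + 1e-9, side="right") - 1
    return classes[idx].astype(np.int64)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_features(recording: RawRecording, track: AnnotationTrack,
                      combination: SensorCombination = SensorCombination.C1,
                      participant_id: str = "",
                      envelope_cfg: EnvelopeConfig | None = None,
                      normalize: bool = False,
                      emg_refs: tuple | None = None) -> FeatureSequence:
    """Build the 10 Hz feature sequence for one participant.

    Column order follows ``combination.channel_names``: per site WC, WCW,
    Thor, UA, FA first acc_x..acc_z then gyr_x..gyr_z, EMG channels last.
    Static-posture normalization of the EMG envelope is off by default and
    requires the participant's reference levels when enabled.  All columns
    are truncated to the shortest processed channel.
    """
    envelope_cfg = envelope_cfg or EnvelopeConfig()
    cols = []
    for site in combination.sites:
        ch = recording.sites[site]
        cols.append(downsample_imu(ch.accel))
        cols.append(downsample_imu(ch.gyro))
    if combination.with_emg:
        if recording.emg is None or recording.emg.size == 0:
            raise ValueError("combination requires EMG but recording has none")
        envs = []
        for m in range(len(EMG_CHANNELS)):
            env = emg_envelope(recording.emg[:, m], envelope_cfg)
            if normalize:
                if emg_refs is None:
                    raise ValueError("normalize=True requires emg_refs")
                env = normalize_emg(env, emg_refs[m])
            envs.append(env)
        cols.append(np.column_stack(envs))
    T = min(c.shape[0] for c in cols)
    X = np.column_stack([c[:T] for c in cols])
    y = labels_at_10hz(track, T)
    return FeatureSequence(X=X, y=y, participant_id=participant_id,
                           combination=combination,
                           channel_names=combination.channel_names)
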