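"""Activity classes and sensor sites for wheelchair-related shoulder loading.

Manual wheelchair users load the shoulder through a small repertoire of
everyday activities: propelling the chair, short-range maneuvering
("dribbling"), weight-relief lifts off the rims, transfers in and out of the
chair, handling material at shelf height, arm-crank ergometry, and quieter
desk or resting postures.  This module enumerates those eight activity
classes and the five body/chair sensor sites used to record them, together
with the parametric signal signatures the synthetic cohort generator uses to
emulate each activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum


class ActivityClass(IntEnum):
    """The eight shoulder-loading activities of daily living (SL-ADL).

    The integer value fixes the class order used everywhere downstream
    (label vectors, confusion-chart rows/columns, summary tables).
    """

    WRL = 0        # weight relief lift: push up on the rims, hold, sit back
    DRIBBLING = 1  # intermittent short-range propulsion, <= 3 pushes / 3 m
    WCPROP = 2     # continuous wheelchair propulsion (treadmill pace)
    MMH = 3        # manual material handling: pick/place a 2 kg weight
    DESK = 4       # desk work: typing, mouse, phone
    STAT = 5       # stationary sitting, minor hand movements allowed
    TRANSFER = 6   # transfer between wheelchair and couch
    ARMCRANK = 7   # arm crank ergometer work at 60 rpm

    @property
    def code(self) -> str:
        return _CODES[self]

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_code(cls, code: str) -> "ActivityClass":
        try:
            return _BY_CODE[code]
        except KeyError:
            raise ValueError(f"unknown activity code {code!r}; "
                             f"expected one of {sorted(_BY_CODE)}") from None


_CODES = {
    ActivityClass.WRL: "WRL",
    ActivityClass.DRIBBLING: "Dribbling",
    ActivityClass.WCPROP: "WCprop",
    ActivityClass.MMH: "MMH",
    ActivityClass.DESK: "Desk",
    ActivityClass.STAT: "Stat",
    ActivityClass.TRANSFER: "Transfer",
    ActivityClass.ARMCRANK: "ArmCrank",
}
_LABELS = {
    ActivityClass.WRL: "Weight relief lift",
    ActivityClass.DRIBBLING: "Dribbling",
    ActivityClass.WCPROP: "Wheelchair propulsion",
    ActivityClass.MMH: "Manual material handling",
    ActivityClass.DESK: "Deskwork",
    ActivityClass.STAT: "Stationary",
    ActivityClass.TRANSFER: "Transfer",
    ActivityClass.ARMCRANK: "Arm cranking",
}
_BY_CODE = {c: a for a, c in _CODES.items()}

N_CLASSES = len(ActivityClass)

#: classes during which the wheelchair wheel actually rotates; every other
#: class must show a wheel gyroscope consistent with zero plus noise
WHEEL_MOTION_CLASSES = frozenset({ActivityClass.DRIBBLING, ActivityClass.WCPROP})


class SensorSite(IntEnum):
    """The five inertial sensor placements (chair frame, wheel, body)."""

    WC = 0    # wheelchair frame
    WCW = 1   # wheelchair wheel
    THOR = 2  # thorax
    UA = 3    # right upper arm (carries the two EMG channels)
    FA = 4    # right forearm

    @property
    def code(self) -> str:
        return _SITE_CODES[self]

    @property
    def modalities(self) -> frozenset:
        mods = {"accel3", "gyro3"}
        if self is SensorSite.UA:
            mods.add("emg2")
        return frozenset(mods)


_SITE_CODES = {
    SensorSite.WC: "WC",
    SensorSite.WCW: "WCW",
    SensorSite.THOR: "Thor",
    SensorSite.UA: "UA",
    SensorSite.FA: "FA",
}

SITES = tuple(SensorSite)

#: the two bipolar surface-EMG channels on the upper-arm unit
EMG_CHANNELS = ("biceps", "deltoid")

IMU_RATE_HZ = 100.0
EMG_RATE_HZ = 1000.0
TARGET_RATE_HZ = 10.0

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class SiteMotion:
    """Amplitude of the modulated movement component at one sensor site.

    accel_amp in m/s^2, gyro_amp in deg/s; both scale the class's
    modulation waveform before it is projected on fixed axis directions.
    """

    accel_amp: float = 0.0
    gyro_amp: float = 0.0


@dataclass(frozen=True)
class ActivitySignature:
    """Parametric template for one activity class.

    The generator composes, per site: a gravity component along a
    class-specific posture direction, a movement component equal to the
    class's modulation waveform scaled by the site amplitudes, the wheel
    rotation profile on the wheel gyroscope, and additive Gaussian noise.

    wheel_mode is "off" (wheel still), "continuous" (steady rotation with a
    push-cadence ripple, as in treadmill propulsion) or "bouts" (short
    on/off rotation episodes that start and end at zero, as in dribbling).
    modulation is "cycle" (sinusoid at arm_cycle_freq), "bouts"
    (smooth-edged on/off episodes carrying an arm_cycle_freq oscillation)
    or "hash" (low-pass-filtered random movement, for desk/stationary
    fidgeting).
    """

    activity: ActivityClass
    modulation: str = "cycle"
    arm_cycle_freq: float = 1.0          # Hz
    bout_period: float = 5.0             # s, for "bouts" modulation
    bout_duty: float = 0.5               # fraction of the period active
    wheel_mode: str = "off"
    wheel_omega: float = 0.0             # deg/s, steady or bout peak
    wheel_ripple: float = 0.0            # deg/s, push-cadence ripple
    site_motion: dict = field(default_factory=dict)   # SensorSite -> SiteMotion
    posture_pitch: dict = field(default_factory=dict)  # SensorSite -> radians
    emg_burst_level: tuple = (0.1, 0.1)  # (biceps, deltoid) envelope scale

    @property
    def wheel_moves(self) -> bool:
        return self.wheel_mode != "off"


def _sig(activity, **kw) -> ActivitySignature:
    return ActivitySignature(activity=activity, **kw)


# Per-class templates.  Amplitudes are order-of-magnitude realistic for the
# respective activities (propulsion wheel speed ~0.85 m/s on a ~0.3 m radius
# wheel gives ~160 deg/s; lifts and transfers produce multi-m/s^2 bursts on
# the arm and thorax; desk work and quiet sitting are near-static).  The
# posture pitch tilts the per-site gravity direction so that low-motion
# classes remain separable through their static arm/trunk attitude.
#
# The confusable pairs are deliberate: dribbling and propulsion share the
# arm-level push pattern and differ mainly in the wheel rotation profile
# (intermittent bouts vs continuous), and weight-relief lifts share the
# arm-level burst pattern with transfers, which differ mainly in the trunk
# excursion.  A classifier restricted to a single arm sensor therefore
# loses exactly the cues that the full five-sensor setup provides.
SIGNATURES: dict[ActivityClass, ActivitySignature] = {
    ActivityClass.WRL: _sig(
        ActivityClass.WRL,
        modulation="bouts", arm_cycle_freq=0.4, bout_period=6.0, bout_duty=0.5,
        site_motion={
            SensorSite.UA: SiteMotion(2.8, 50.0),
            SensorSite.FA: SiteMotion(2.4, 40.0),
            SensorSite.THOR: SiteMotion(0.5, 5.0),
            SensorSite.WC: SiteMotion(0.3, 2.0),
        },
        posture_pitch={SensorSite.UA: 0.45, SensorSite.FA: 0.35},
        emg_burst_level=(1.6, 1.3),
    ),
    ActivityClass.DRIBBLING: _sig(
        ActivityClass.DRIBBLING,
        modulation="cycle", arm_cycle_freq=1.1,
        wheel_mode="bouts", wheel_omega=120.0, bout_period=6.0, bout_duty=0.5,
        site_motion={
            SensorSite.UA: SiteMotion(1.6, 48.0),
            SensorSite.FA: SiteMotion(2.0, 75.0),
            SensorSite.THOR: SiteMotion(0.6, 6.0),
            SensorSite.WC: SiteMotion(0.7, 8.0),
        },
        posture_pitch={SensorSite.UA: 0.4, SensorSite.FA: 0.3},
        emg_burst_level=(0.9, 0.7),
    ),
    ActivityClass.WCPROP: _sig(
        ActivityClass.WCPROP,
        modulation="cycle", arm_cycle_freq=1.0,
        wheel_mode="continuous", wheel_omega=160.0, wheel_ripple=30.0,
        site_motion={
            SensorSite.UA: SiteMotion(1.5, 45.0),
            SensorSite.FA: SiteMotion(2.0, 80.0),
            SensorSite.THOR: SiteMotion(0.6, 6.0),
            SensorSite.WC: SiteMotion(0.5, 4.0),
        },
        posture_pitch={SensorSite.UA: 0.4, SensorSite.FA: 0.3},
        emg_burst_level=(0.8, 0.6),
    ),
    ActivityClass.MMH: _sig(
        ActivityClass.MMH,
        modulation="bouts", arm_cycle_freq=0.45, bout_period=4.5, bout_duty=0.6,
        site_motion={
            SensorSite.UA: SiteMotion(2.6, 48.0),
            SensorSite.FA: SiteMotion(2.6, 45.0),
            SensorSite.THOR: SiteMotion(1.4, 14.0),
        },
        posture_pitch={SensorSite.UA: 0.55, SensorSite.FA: 0.45,
                       SensorSite.THOR: 0.12},
        emg_burst_level=(1.8, 1.1),
    ),
    ActivityClass.DESK: _sig(
        ActivityClass.DESK,
        modulation="hash",
        site_motion={
            SensorSite.UA: SiteMotion(0.15, 2.0),
            SensorSite.FA: SiteMotion(0.5, 9.0),
        },
        posture_pitch={SensorSite.UA: 0.25, SensorSite.FA: 1.2,
                       SensorSite.THOR: 0.2},
        emg_burst_level=(0.12, 0.08),
    ),
    ActivityClass.STAT: _sig(
        ActivityClass.STAT,
        modulation="hash",
        site_motion={
            SensorSite.UA: SiteMotion(0.08, 1.2),
            SensorSite.FA: SiteMotion(0.18, 3.0),
        },
        posture_pitch={},
        emg_burst_level=(0.05, 0.04),
    ),
    ActivityClass.TRANSFER: _sig(
        ActivityClass.TRANSFER,
        modulation="bouts", arm_cycle_freq=0.4, bout_period=6.5, bout_duty=0.5,
        site_motion={
            SensorSite.UA: SiteMotion(2.8, 50.0),
            SensorSite.FA: SiteMotion(2.4, 42.0),
            SensorSite.THOR: SiteMotion(3.0, 40.0),
            SensorSite.WC: SiteMotion(0.6, 5.0),
        },
        posture_pitch={SensorSite.THOR: 0.3, SensorSite.UA: 0.45,
                       SensorSite.FA: 0.35},
        emg_burst_level=(1.4, 1.5),
    ),
    ActivityClass.ARMCRANK: _sig(
        ActivityClass.ARMCRANK,
        modulation="cycle", arm_cycle_freq=1.0,   # 60 rpm
        site_motion={
            SensorSite.UA: SiteMotion(2.0, 60.0),
            SensorSite.FA: SiteMotion(3.0, 100.0),
            SensorSite.THOR: SiteMotion(0.4, 4.0),
        },
        posture_pitch={SensorSite.UA: 0.6, SensorSite.FA: 0.7},
        emg_burst_level=(0.9, 0.8),
    ),
}
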