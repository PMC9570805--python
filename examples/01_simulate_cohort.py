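"""Generate a small synthetic cohort and inspect one recording.

Each virtual participant performs all eight shoulder-loading activities
once, in randomized order; five IMU sites record at 100 Hz and the two
upper-arm EMG channels at 1000 Hz, with a contiguous annotation track.
"""

import numpy as np

from sladl import (CohortConfig, ScheduleConfig, SensorSite, generate_cohort,
                   WHEEL_MOTION_CLASSES)

config = CohortConfig(n_participants=3,
                      schedule=ScheduleConfig(min_duration=8.0,
                                              max_duration=12.0))
dataset = generate_cohort(3, config, seed=42)

profile, recording, track = dataset.participants[0]
print(f"participant {profile.participant_id}: "
      f"{recording.duration:.1f} s, {recording.n_imu_samples} IMU samples, "
      f"{recording.emg.shape[0]} EMG samples")
print(f"amplitude scales: " +
      ", ".join(f"{k}={v:.2f}" for k, v in profile.amp_scale.items()))
print("\nannotated intervals (start-end, activity):")
wheel = recording.sites[SensorSite.WCW].gyro[:, 2]
for start, end, activity in track.intervals:
    seg = np.abs(wheel[int(start * 100):int(end * 100)])
    flag = "wheel moving" if activity in WHEEL_MOTION_CLASSES else ""
    print(f"  {start:6.1f}-{end:6.1f} s  {activity.code:10s} "
          f"mean |wheel gyro| {seg.mean():6.1f} deg/s  {flag}")

# The wheel gyroscope separates wheel-motion activities from the rest:
# during dribbling/propulsion its mean magnitude is far above the noise
# floor (~2 deg/s); during every other activity it stays at that floor.
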