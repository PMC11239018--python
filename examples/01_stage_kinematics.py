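"""Stage kinematics: step size, speed range, and micro-step selection.

A 400 steps/rev stepper drives an 8 mm lead screw through a 3:1 pulley
reduction, so one full step is 6.67 um of platform travel.  The driver
sustains a fixed pulse rate, so micro-stepping trades top speed for
resolution — the same motors cover fast ciliates (~4600 um/s at full
steps) and slow amoebae (~144 um/s at 1/32 steps).
"""

from trackscope.stage import (
    MICROSTEPS,
    StageConfig,
    max_speed_um_s,
    select_microstep,
    step_size_um,
)

cfg = StageConfig()  # 400 steps/rev, 3:1 gears, 8 mm lead, 690 Hz pulses

print("microstep  step size (um)  top speed (um/s)")
for m in MICROSTEPS:
    c = cfg.with_microstep(m)
    print(f"{m:9d}  {step_size_um(c):14.4f}  {max_speed_um_s(c):16.2f}")

for organism, speed in [("Bursaria (fast ciliate)", 1775.0), ("Stentor", 500.0), ("Amoeba", 21.0)]:
    m = select_microstep(speed, cfg)
    print(
        f"\n{organism} at {speed:.0f} um/s -> microstep 1/{m} "
        f"(stage top speed {max_speed_um_s(cfg.with_microstep(m)):.0f} um/s, "
        ">= twice the organism speed)"
    )
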