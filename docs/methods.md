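# Methods

This note documents the models, defaults and numerical choices behind
`trackscope`, and what the simulator does and does not claim about real
instruments.

## Stage kinematics

The stage model is an ideal stepper/lead-screw transmission: micro-step
size `lead_um / (steps_per_rev · gear_ratio · microstep)` with defaults
8000 µm, 400, 3 and micro-stepping in {1, 2, 4, 8, 16, 32}. The driver
is modelled as sustaining a fixed pulse frequency `pulse_rate_hz`
independent of the micro-stepping divisor, so top speed scales exactly
as `1/m`. `pulse_rate_hz` is a calibration constant, default **690 Hz**,
chosen so the full-step top speed with default geometry is 4600 µm/s —
the speed the physical instrument reaches; measured instruments show a
slightly sub-ideal ratio across the micro-stepping range (firmware
overhead), which this ideal model deliberately ignores.

Micron→step quantisation rounds half away from zero so symmetric jogs
produce symmetric step counts; the round-trip error is bounded by half
a step. The virtual stage executes the textual dialect
(`MOVE axis steps Frate`, `HALT`, `POS?`) that a serial firmware would:
the dialect is self-defined because no public firmware protocol exists
for this class of instrument, and the simulator and any future hardware
driver are meant to share it. Motion integrates at
`min(commanded, pulse ceiling) · step_size` per second, clamps at
±`travel_um` per axis (setting a limit flag), and position changes only
through `advance` — there is no homing or limit switch, matching the
open-frame instrument. Acceleration ramps and jerk are not modelled.

## Synthetic optics and organisms

The generator emulates the study conditions of the instrument: a
640×480 grayscale view of an 18 cm × 18 cm arena, organisms of
10 µm–2 mm body size moving at 0.1 µm/s–2 mm/s. Defaults: pixel scale
1 µm/px (a mid-range magnification where the default 120 µm organism
fills ~1/5 of the frame height), bright-field background 200 with
organism contrast −120, Gaussian read noise σ = 3 gray levels — a
clean but not noise-free camera. Dark field is the same model with a
low background and positive contrast.

Motility models are phenomenological: `ballistic`/`drift` (constant
velocity), `run_tumble` (Poisson tumbles to a uniform heading at
`turn_rate_hz`), `stop_go` (two-state Markov switch with exit rates
`dwell_exit_hz`; a fresh heading on each resume; the rendered ellipse
becomes an equal-area circle while stationary, echoing trumpet↔sphere
shape change), and `circular_lurch` (constant angular bias). Walls
reflect both position and heading; with the default arena the walls are
effectively never met, which matches the instrument's motivation of
letting organisms swim without wall interactions.

The organism is a rigid anti-aliased ellipse — no cilia, pseudopodia,
deformation, defocus or PSF. Consequences: the native tracker's
segmentation task is easier than on real imagery, so passing tests
demonstrate the correctness of the *loop* (geometry, timing, control
logic, bookkeeping), not tracker robustness to real biological
appearance. That robustness is exactly what the pluggable CSRT backend
is for on real data.

Per-frame noise is drawn from a bank of 8 pre-generated Gaussian
fields, selected and cyclically shifted at random each frame.
Marginally each pixel remains N(background, σ²) and fields stay
spatially white; only long-range temporal correlations are introduced,
which nothing downstream is sensitive to. This cuts rendering cost
several-fold and keeps sessions deterministic per seed (a single
generator drives noise, motility and initial heading, so telemetry is
byte-identical across runs with the same seed).

## Tracker

The native backend estimates the background as the median of the frame
border pixels pooled over the first five frames, and the noise level as
a MAD estimate from the same border. Foreground is
`|pixel − background| > max(10, 3σ̂)`; components smaller than 5 px are
discarded (at σ = 3 the threshold sits near 3.3σ, so isolated noise
pixels would otherwise appear as components). Among remaining
components the one whose centroid is nearest the previous box centre
wins; ties break deterministically (larger area, then smaller x, then
smaller y). Confidence is current component area over the area at
initialisation, capped at 1; loss is confidence strictly below a
threshold (default 0.2). On loss the previous box is returned rather
than raising, and the controller halts the stage — the safest policy
for a real instrument and the simplest to test; re-acquisition is out
of scope. A discriminative-correlation-filter backend (OpenCV CSRT) is
available behind the same contract when `opencv-python` is installed;
it is intentionally not re-implemented.

## Controller

Dead zone: the central `zone_fraction` (default 1/3) of each frame
dimension, boundary inclusive. The fraction is a design choice — a
third balances re-centring frequency against escape margin — and is
configurable. Corrections are proportional jogs to the exact centre
(`−axis_sign · offset · pixel_scale`), clipped at `max_jog_um`
(default 2000 µm) so a tracker glitch cannot fling the stage; speed
limiting comes from the stage model, with the commanded rate defaulting
to the stage's top speed. One jog may be in flight per axis; new
corrections wait for completion, so commands never stack. `axis_sign`
absorbs mount orientation; with the simulator's rendering convention
(pixel offset = (organism − stage)/pixel scale) the correct default is
(−1, −1), making the stage chase the organism. Velocity feed-forward
and PID dynamics are out of scope; whether real firmware scales speed
with offset is unknown, and a fixed-rate proportional jog is the
simplest law consistent with "re-centre until inside the zone".

## Telemetry and reconstruction

Records are emitted on a 50 ms grid. The control loop defaults to
30 Hz (a conservative desktop tracking cadence; the real loop rate is
hardware-dependent), which does not divide 50 ms evenly, so tick
samples are linearly interpolated onto the grid — zero-order hold would
alias up to ~8 px at 500 µm/s. Frame coordinates are stored relative to
the frame centre (signed integers); stage positions in µm with exactly
three decimals, making the CSV dialect bit-exact under round trips.

Reconstruction keeps the in-frame cumulant in µm, adding per-sample
pixel deltas × pixel scale — algebraically identical to scaling the
summed pixel displacement for a constant scale, and well-defined across
tracker re-initialisations. The platform term uses the logged true
stage position; the velocity×50 ms integration variant used by original
firmware is also provided (`update_platform_displacement`) so its
quantisation error is measurable in simulation against the true
position.

## Motion analysis

Speeds are forward differences at interval midpoints; the default
5-sample centred moving average (250 ms) suppresses the spikes that
discrete stage jogs leave in reconstructed logs without hiding
contraction-scale events. On clean ground-truth trajectories no
smoothing is needed and `window=1` is appropriate. Summaries are
duration-weighted; total distance is always the raw arc length
(smoothing does not conserve the sum at the edges). Bout segmentation
uses hysteresis with `v_on = 2·v_off` by default; sub-`min_dwell`
segments merge into the longer neighbour (ties to the earlier), applied
iteratively shortest-first. Body-length normalisation takes the body
length as an explicit argument — species conventions vary too much to
assume one.

## Calibration

USAF arithmetic is exact (`2^(G+(E−1)/6)`, `1000/RES_LP`). Pixel-scale
estimation thresholds the profile at its mean level and takes the mean
spacing of bright-run centres as the bar period; mean-level crossing is
more robust than derivative zero-crossings on short hand-sampled
profiles, and a 10-gray-level contrast floor rejects ripple. Profiles
sampled from images average a 3 px band normal to the line
(configurable). Automatic localisation of chart elements and MTF
computation are out of scope. The brightness metric is the raw gray
mean as a percentage of 255; specific ring-light percentages are
hardware measurements, not properties of this code.

## Problem sizes and verification

The test suite runs closed-loop sessions of 5 simulated minutes at
30 Hz (9000 ticks) across three seeds and two motility models at
500–1775 µm/s for the retention property, a 60 s session for
reconstruction fidelity, and 2000 s ground-truth-only stop-and-go
simulations (~650 bouts) for parameter recovery — sizes chosen so
statistical tolerances (5 % on speed, 10 % on mean dwells) sit several
standard errors away from the truth under the configured conditions.
Multi-hour real-organism tracks are not reproduced in simulation; the
5-minute retention property is the desk-scale stand-in for them.

## Known limitations

- Single organism per scene; occlusion and re-identification untested
  beyond contract level.
- No Z axis anywhere (the physical instrument's Z is manual).
- Ideal kinematics: no backlash, vibration, missed steps or
  acceleration limits.
- The native tracker is validated on synthetic scenes only; real
  imagery should use the CSRT backend.
- Live capture and physical serial I/O are interface stubs; the
  command dialect is shared but untested against hardware.
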