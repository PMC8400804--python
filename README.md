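# fuzzyfes

A desk-scale software model of a digital **fuzzy feedback controller (FFC)**
for closed-loop **functional electrical stimulation (FES)** of knee
extension, of the kind synthesized into FPGA logic for wearable
neuroprostheses. The package is written for control and rehabilitation
engineers who want to study — bit-exactly — how a fixed-point fuzzy
controller behaves before committing it to hardware.

In a closed-loop FES knee exercise, surface electrodes stimulate the
quadriceps so the shank extends from its hanging position (0°) toward a
target angle (70°, 40° or 30°). A sensor reports the actual knee angle
θ_act; the controller compares it with the reference θ_ref and modulates
the **stimulus pulse width** (100–500 µs) so the target is reached without
overstimulation — the main driver of early muscle fatigue.

## The controller

A zero-order Takagi–Sugeno fuzzy controller with two inputs,

```
E_k  = θ_ref − θ_act,k          (error, deg)
dE_k = E_k − E_{k−1}            (change in error, deg)
```

each clamped to [−20°, 20°] and mapped onto an 8-bit scale
`x ↦ ⌊(x+20)·255/40⌋`. Five triangular membership functions
(NB, NS, ZE, PS, PB) with integer degrees 0–255 fuzzify each input; a
5×5 rule grid is evaluated with min-inference (`min_i = min(µ_E, µ_dE)`),
and the crisp output is the floored singleton centre-of-gravity

```
defuzzy = ⌊ Σ_i min_i·c_i / Σ_i min_i ⌋ ,   pulse = defuzzy × 10 µs
```

with a singleton table `c` (VS…VB, values 10–50) per reference angle. All
divisions are floor divisions applied once at the end of each rational
expression — exactly what integer hardware computes. A parallel
floating-point pipeline (`flc_step_float`) provides the continuous control
law the integer datapath quantizes, and the two never differ by more than
2 defuzzy units.

Around the datapath the package simulates, at a 1 µs tick, the ADC
data-acquisition state machine (Idle → SOC → Delay → EOC handshake with an
8-bit converter, 100 ms sampling), the three-cycle error-conversion state
machine, and the 20–50 Hz PWM stage. A configurable knee plant — one-pole
pulse-width→torque activation feeding nonlinear second-order shank
dynamics — closes the loop for step-response studies.

## Worked example

The controller's register-level arithmetic, evaluated from the shell:

```
$ flc-eval --ref 70 --act 4 --prev-err 70 --float
err      = 66
derr     = -4
fired    = min10=99, min15=155
defuzzy  = 43
pulse    = 430 us
prev_err = 66
defuzzy (float) = 43.8000
```

The error 66° clamps to +20° (scale 255, full PB membership); the change
−4° scales to 102, splitting membership between NS (99) and ZE (155).
Rules 10 (PB, NS → BG = 42) and 15 (PB, ZE → VB = 45) fire, and
⌊(99·42 + 155·45)/254⌋ = 43, i.e. a 430 µs stimulus pulse. The continuous
pipeline gives 43.8 — a 1.8 % quantization error.

Closed-loop step responses with the shipped plant defaults:

```
$ step-response --ref 70 --duration 10
{"ref": 70, "mode": "integer", "rise_time_s": 2.011, "settling_time_s": 3.343,
 "overshoot_deg": 0.0, "steady_state_error_deg": 0.258}
$ step-response --ref 40 --duration 10
{"ref": 40, "mode": "integer", "rise_time_s": 1.631, "settling_time_s": 2.81,
 "overshoot_deg": 0.446, "steady_state_error_deg": 0.444}
$ step-response --ref 30 --duration 10
{"ref": 30, "mode": "integer", "rise_time_s": 1.391, "settling_time_s": 2.31,
 "overshoot_deg": 0.25, "steady_state_error_deg": 0.25}
```

Smaller targets are reached faster; every target settles in its 2 % band
with sub-degree steady-state error and well under a degree of overshoot —
the behaviour that matters clinically, since overshoot and sustained
excess pulse width both mean overstimulation.

Other entry points: `fsm-trace` (cycle-level event log of the acquisition /
conversion / PWM pipeline), `sweep` (synthetic 0→90° potentiometer ramp
fixtures, optionally pushed through the controller), and `compare`
(per-sample percentage error between two traces). All accept `--config`
with a YAML file overriding the controller tables and plant parameters
(see `fuzzyfes.config`).

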