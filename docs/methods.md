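# Methods

## Scope and model

`fuzzyfes` models a digital fuzzy feedback controller for closed-loop FES
knee extension at three levels of abstraction:

1. **Datapath** (`fuzzyfes.flc`) — the fixed-point Takagi–Sugeno control
   law, arithmetic-exact with respect to integer hardware.
2. **Cycle level** (`fuzzyfes.fsm`) — the acquisition, error-conversion
   and PWM state machines on a 1 µs tick.
3. **Closed loop** (`fuzzyfes.plant`, `fuzzyfes.loop`) — a
   knee-extension plant sampled by the controller at 100 ms.

## The integer datapath and its quantization conventions

Crisp errors are clamped to ±20° and scaled by `⌊(x+20)·255/40⌋`.
Two conventions are deliberate and load-bearing:

* **End-floor division.** Every rational expression (scaler, triangle
  edges, centre of gravity) is evaluated as an integer product first and
  floored once at the end, e.g. `⌊255·(x−a)/(b−a)⌋`. Pre-dividing
  (`(255/(b−a))·(x−a)`) — a tempting micro-optimization in hardware
  pseudocode — truncates the slope to an integer and does **not**
  reproduce the documented register values; the end-floor form does,
  bit for bit.
* **Shoulder membership functions.** The outermost sets are encoded as
  shoulders, NB = (0, 0, 63) and PB = (191, 255, 255), so a fully clamped
  input carries full membership 255. Literal symmetric triangles would
  return 0 at the scale ends and starve the rule base exactly when the
  error is largest.

The **previous-error register stores the raw, unclamped error**; clamping
happens only inside the scaler. This matters for the change-in-error: a
register history of 70 followed by an error of 66 yields dE = −4 even
though both errors individually clamp to +20.

At power-on both registers are zero, so the first registered output is the
ME singleton of the selected table (38 / 22 / 16 for the 70° / 40° / 30°
tables). The defuzzified output is held in a 16-bit register; values never
exceed 50, so the width only fixes trace formats. `defuzzify` guards the
(unreachable with the shipped sets, whose memberships always sum to
254–255) all-rules-zero case with an explicit error, because user-supplied
membership tables can have coverage holes.

The floating-point pipeline applies the same clamp, sets, rule grid and
singleton tables on the degree domain with real memberships in [0, 1]. It
is the package's quantization oracle: on the exhaustive
(err, derr) ∈ [−25, 25]² grid the integer output stays within 2 defuzzy
units of it, and along closed-loop angle sequences within 1 unit.

## Cycle-level timing

The simulator ticks at 1 µs (the 1 MHz clock a 50 MHz master would be
divided down to; the divider itself has no behavioural consequence at this
granularity and is abstracted). Acquisition walks Idle → SOC (80 µs) →
Delay → EOC (80 µs); the modelled converter drops its interrupt line
`latency` µs into the Delay state (default 75 µs, the figure for an 8-bit
successive-approximation converter of this class), giving the 235 µs
acquisition and, with the three-cycle Sample → Calculate → Store datapath,
a 238 µs trigger-to-pulse-update path. A latency of 0 models a testbench
holding the interrupt low; the Delay state is then transited in one cycle
(161 µs total) — the transit time is an assumption, as timing diagrams of
such testbenches only show "a short duration". Sampling triggers repeat
every 100 ms, the first 100 ms after reset (the periodicity is documented;
the first-sample offset is a package choice). The two-bit dip-switch
decoders use ascending code order (00→70°, 01→40°, 10→30°, 11 reserved →
70°; 00→20 Hz … 11→50 Hz), configurable because hardware bit assignments
are wiring choices. PWM width changes latch at the next period boundary,
never mid-pulse, to avoid glitch pulses.

## The knee plant

Two stages, both package models with package defaults (no published
parameter set is reproduced):

* **Activation:** dT_a/dt = (G·pw − T_a)/τ — first-order recruitment of
  quadriceps torque from pulse width, advanced with the exact exponential
  update.
* **Shank dynamics:** J·θ̈ = T_a − m·g·l·sin θ − B·θ̇ − K·(θ − θ_r), with
  hard stops at 0° and 90° (velocity zeroed against the stop). θ = 0 is
  the hanging shank; positive is extension.

Defaults (units SI unless noted): J = 1.2 kg·m², m·g·l = 0.9716 N·m,
B = 4.6 N·m·s/rad, K = 2.5789 N·m/rad, θ_r = 5.577°, G = 0.01 N·m/µs,
τ = 0.35 s.

**How the defaults were chosen.** Near its target the integer controller
sits on a constant-output plateau (defuzzy 38 / 22 / 16 for the three
tables), so each closed-loop equilibrium is fixed by the static balance
`G·10·defuzzy = m·g·l·sin θ + K·(θ − θ_r)`. The three gravity/stiffness
parameters were solved so those plateaus balance at 69.75°, 40.45° and
30.25° — inside every 2 % band, midway between ADC quantization
thresholds (which avoids limit-cycling of the sampled integer loop around
a code boundary). This placement requires a positive elastic resting
angle θ_r and a stiffness-dominated moment balance; physiologically this
corresponds to a limb with substantial passive elastic stiffness (as in
spastic or contractured knees) rather than a free-swinging pendulum. It
is a deliberate modelling choice: with θ_r = 0 no non-negative
(m·g·l, K, G) triple balances all three plateau outputs inside their
bands, because the plateau ratios 380:220:160 µs are nearly proportional
to the target angles while gravity is strongly concave in θ. A
consequence of θ_r > 0 is that the unstimulated shank rests ≈3–4° above
the hard stop; passivity tests therefore check convergence to this
passive equilibrium with monotonically decreasing energy. J, B and τ were
then fixed by a one-time grid scan for an overdamped response in the
regime of a few seconds with robust metric ordering across targets; with
the shipped values the integer loop measures rise times of
1.39 / 1.63 / 2.01 s and settling times of 2.31 / 2.81 / 3.34 s for
30° / 40° / 70°.

**Integration.** Fixed-step classical RK4 at a 1 ms inner step with
zero-order hold on the pulse width between 100 ms controller samples. The
activation stage advances by its exact exponential on either side of each
dynamics step (Strang splitting), keeping the stage-coupling error at
second order; halving the inner step moves a 5 s trajectory by well under
0.01°.

## Closed-loop metrics

Computed on the dense (inner-step) trajectory: rise time = first 10 %→90 %
crossing interval of the reference; settling time = last entry into the
±2 % band (a trajectory whose final fifth leaves the band raises an
explicit not-settled error); overshoot = max(θ) − ref, floored at 0,
in degrees; steady-state error = |ref − mean θ| over the final 1 s. The
10–90 % rise convention and the 1 s steady-state window are package
choices (alternatives exist; both are configurable arguments). The
percentage-error comparison statistic rounds each per-sample error
|ref−test|/ref·100 to one decimal and averages the rounded values, which
is how such comparison tables are conventionally printed; zero-reference
samples are excluded with a warning.

## Synthetic fixtures, noise, and what the tests do not show

The sweep fixture emulates a bench test in which a potentiometer standing
in for the knee is rotated 0→90° and held: a piecewise-linear ramp sampled
at 100 ms. It exercises the full code path (scaling, saturation at both
table ends, FSM timing) but is noise-free and monotone; real goniometer
data carry sensor noise, soft-tissue artefact and non-monotone segments.
Gaussian sensor noise (explicit standard deviation and seed) can be
enabled for robustness demonstrations but is off by default. The plant
omits muscle fatigue, antagonist co-contraction, torque saturation and
subject-specific identification, so passing closed-loop tests demonstrate
the controller's quantization fidelity and qualitative loop behaviour —
not clinical performance on a specific limb. The voltage domain of the
sensor chain is not modelled; fixtures are specified in degrees and pass
through the 8-bit code conversion.

## Numerical and degenerate-input conventions

* Triangle evaluation order: the peak test (`x == b`, returning 255)
  precedes the boundary tests, so shoulders are handled naturally and a
  fully degenerate triangle (a = b = c) is 255 at its single point and 0
  elsewhere.
* `scale_to_digital` is total: any integer input is clamped before
  scaling, and scaling is idempotent under clamping.
* Angle→code conversion floors (`⌊θ·255/90⌋`), as does code→degrees
  (`⌊code·90/255⌋`); the round trip therefore never reads back above the
  true angle and loses at most one degree plus one code width.
* PWM widths outside 100–500 µs are clamped with a warning; a width
  reaching the stimulation period is an error.
* Hard stops clamp the angle and zero the velocity component pushing into
  the stop, preserving energy dissipation.

## Known limitations

The cycle simulator is event-faithful but not gate-faithful: it reproduces
state durations, handshake line levels and register-update instants, not
intra-cycle combinational timing. The plant is a deliberately simple
surrogate whose constants were calibrated to the controller tables (see
above), so absolute rise/settling times should not be read as predictions
for any physical limb. The float pipeline is a clean-room continuous
counterpart of the integer datapath, not a re-implementation of any
particular modelling tool's fuzzy engine.
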