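"""Cycle-level simulation of the controller's digital front end.

Everything here ticks on a 1 us clock (the 1 MHz clock the hardware derives
from its 50 MHz master; the divider itself is abstracted away).  The module
models four pieces of the feedback controller:

* the ADC data-acquisition finite state machine (Idle -> SOC -> Delay ->
  EOC) with its chip-select / read / write handshake lines,
* the converter device it talks to (8-bit successive-approximation ADC with
  a configurable conversion latency and an active-low interrupt),
* the three-state error-conversion FSM that latches a sample, computes the
  error and change-in-error, and exposes the combinational fuzzy outputs,
* the PWM stage that turns the pulse-width register into stimulus pulses at
  20-50 Hz.

Angle <-> code conversions use the hardware's integer arithmetic exactly:
an 8-bit code spans 0-90 degrees, so code 101 reads back as 35 degrees and
113 as 39 degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor
from typing import Callable, List, Optional, Tuple

from .flc import DefuzzyResult, FlcConfig, default_flc_config, flc_step, reset_defuzzy

__all__ = [
    "TraceEvent",
    "PwmConfig",
    "AcquisitionResult",
    "ErrorConversionResult",
    "AcquisitionTimeout",
    "SAMPLE_PERIOD_US",
    "SOC_DURATION_US",
    "EOC_DURATION_US",
    "decode_ref_setting",
    "decode_freq_setting",
    "angle_to_adc",
    "adc_counts_to_degrees",
    "run_acquisition_cycle",
    "run_error_conversion",
    "generate_pwm",
    "FfcSample",
    "FfcSimulator",
]

#: Interval between sample triggers (100 ms at the 1 us tick).
SAMPLE_PERIOD_US = 100_000
SOC_DURATION_US = 80
EOC_DURATION_US = 80

#: Control-line levels (cs, wr, rd) per acquisition state.
ADC_STATE_OUTPUTS = {
    "Idle": (1, 1, 1),
    "SOC": (0, 0, 1),
    "Delay": (1, 1, 1),
    "EOC": (0, 1, 0),
}

_REF_DECODE = {0b00: 70, 0b01: 40, 0b10: 30, 0b11: 70}
_FREQ_DECODE = {0b00: 20, 0b01: 30, 0b10: 40, 0b11: 50}


class AcquisitionTimeout(RuntimeError):
    """The converter never signalled end of conversion within one period."""


@dataclass(frozen=True)
class TraceEvent:
    """One signal change: cycle stamp in us, signal name, new value."""

    t: int
    signal: str
    value: int


@dataclass(frozen=True)
class PwmConfig:
    """Stimulation frequency and admissible pulse-width range."""

    frequency_hz: int = 50
    min_pulse_us: int = 100
    max_pulse_us: int = 500

    def __post_init__(self) -> None:
        if self.frequency_hz not in (20, 30, 40, 50):
            raise ValueError("stimulation frequency must be 20, 30, 40 or 50 Hz")

    @property
    def period_us(self) -> int:
        return 1_000_000 // self.frequency_hz


def decode_ref_setting(ref_set: int) -> int:
    """Two-bit dip-switch code -> reference angle (00->70, 01->40, 10->30)."""
    try:
        return _REF_DECODE[ref_set]
    except KeyError:
        raise ValueError(f"ref_set must be a 2-bit code, got {ref_set!r}") from None


def decode_freq_setting(freq_sel: int) -> int:
    """Two-bit dip-switch code -> stimulation frequency in Hz (ascending)."""
    try:
        return _FREQ_DECODE[freq_sel]
    except KeyError:
        raise ValueError(f"freq_sel must be a 2-bit code, got {freq_sel!r}") from None


def angle_to_adc(theta: float) -> int:
    """Knee angle in degrees -> 8-bit converter code (0-90 deg spans 0-255)."""
    if theta < 0.0:
        theta = 0.0
    elif theta > 90.0:
        theta = 90.0
    return min(255, floor(theta * 255.0 / 90.0))


def adc_counts_to_degrees(code: int) -> int:
    """8-bit converter code -> integer degrees, ``floor(code * 90 / 255)``."""
    if not 0 <= code <= 255:
        raise ValueError(f"ADC code must be in [0, 255], got {code}")
    return (code * 90) // 255


@dataclass(frozen=True)
class AcquisitionResult:
    sample: int
    duration_us: int
    events: Tuple[TraceEvent, ...]


def run_acquisition_cycle(code: int, latency_us: int = 75, start_t: int = 0,
                          timeout_us: int = SAMPLE_PERIOD_US) -> AcquisitionResult:
    """Tick-simulate one acquisition: SOC (80 us) -> Delay -> EOC (80 us).

    The device pulls its interrupt line low ``latency_us`` after the SOC
    phase completes; a latency of 0 models a testbench that holds the line
    low, in which case the Delay state is transited in a single cycle.  The
    8-bit ``code`` is latched on EOC exit, together with a one-cycle
    ``sample_data_ADC`` pulse.  Total duration is ``160 + max(latency, 1)``.
    """
    if not 0 <= code <= 255:
        raise ValueError(f"ADC code must be in [0, 255], got {code}")
    events: List[TraceEvent] = []
    t = start_t

    def enter(state: str) -> None:
        cs, wr, rd = ADC_STATE_OUTPUTS[state]
        events.append(TraceEvent(t, "state", ord(state[0])))
        events.append(TraceEvent(t, "cs", cs))
        events.append(TraceEvent(t, "wr", wr))
        events.append(TraceEvent(t, "rd", rd))

    enter("SOC")
    for _ in range(SOC_DURATION_US):
        t += 1

    enter("Delay")
    delay_ticks = 0
    while True:
        delay_ticks += 1
        t += 1
        interrupt_low = delay_ticks >= max(latency_us, 1)
        if interrupt_low:
            events.append(TraceEvent(t, "interrupt", 0))
            break
        if delay_ticks > timeout_us:
            raise AcquisitionTimeout(
                f"interrupt never fell within {timeout_us} us")

    enter("EOC")
    for _ in range(EOC_DURATION_US):
        t += 1

    events.append(TraceEvent(t, "sample_data_ADC", 1))
    events.append(TraceEvent(t, "acq_ADC", code))
    enter("Idle")
    return AcquisitionResult(sample=code, duration_us=t - start_t,
                             events=tuple(events))


@dataclass(frozen=True)
class ErrorConversionResult:
    err: int
    derr: int
    cycles: int
    output: DefuzzyResult
    new_prev_err: int
    events: Tuple[TraceEvent, ...]


def run_error_conversion(ref: int, act_deg: int, prev_err: int,
                         config: Optional[FlcConfig] = None,
                         start_t: int = 0) -> ErrorConversionResult:
    """Three-tick Sample -> Calculate -> Store walk of the error FSM.

    Sample latches the reference and actual angle; Calculate forms the
    error; Store forms the change-in-error and rewrites the previous-error
    register.  The fuzzification / inference / defuzzification stages are
    combinational, so the defuzzy and pulse outputs are valid at the Store
    tick — exactly 3 us after the sample-ready pulse.
    """
    config = config or default_flc_config()
    events: List[TraceEvent] = [
        TraceEvent(start_t + 1, "ref_cur", ref),
        TraceEvent(start_t + 1, "act_cur", act_deg),
    ]
    err = ref - act_deg
    events.append(TraceEvent(start_t + 2, "err_cur", err))
    result, new_prev = flc_step(ref, act_deg, prev_err, config)
    derr = err - prev_err
    events.append(TraceEvent(start_t + 3, "derr_cur", derr))
    events.append(TraceEvent(start_t + 3, "defuzzy_out", result.defuzzy))
    events.append(TraceEvent(start_t + 3, "pulse_out", result.pulse))
    return ErrorConversionResult(err=err, derr=derr, cycles=3, output=result,
                                 new_prev_err=new_prev, events=tuple(events))


def generate_pwm(pulse_us: int, cfg: PwmConfig, horizon_us: int,
                 start_t: int = 0) -> Tuple[TraceEvent, ...]:
    """Edge events of a periodic stimulus pulse train.

    The output is high for ``pulse_us`` at the start of every stimulation
    period (period = 1e6 / frequency us).  Widths outside the admissible
    100-500 us range are clamped with a warning; a width reaching the period
    is rejected.
    """
    if pulse_us >= cfg.period_us:
        raise ValueError(
            f"pulse width {pulse_us} us must be below the period "
            f"{cfg.period_us} us")
    if not cfg.min_pulse_us <= pulse_us <= cfg.max_pulse_us:
        clamped = min(max(pulse_us, cfg.min_pulse_us), cfg.max_pulse_us)
        warnings.warn(
            f"pulse width {pulse_us} us outside [{cfg.min_pulse_us}, "
            f"{cfg.max_pulse_us}] us, clamped to {clamped}", stacklevel=2)
        pulse_us = clamped
    events: List[TraceEvent] = []
    t = start_t
    while t < start_t + horizon_us:
        events.append(TraceEvent(t, "pwm_out", 1))
        off = t + pulse_us
        if off >= start_t + horizon_us:
            break
        events.append(TraceEvent(off, "pwm_out", 0))
        t += cfg.period_us
    return tuple(events)


# ---------------------------------------------------------------------------
# full feedback-controller simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FfcSample:
    """Per-acquisition summary of one pass through the feedback controller."""

    trigger_t: int
    code: int
    act_deg: int
    err: int
    derr: int
    defuzzy: int
    pulse: int
    acquisition_us: int
    pulse_update_t: int


@dataclass
class FfcSimulator:
    """Open-loop simulator of the complete digital feedback controller.

    Couples the acquisition FSM, the error-conversion FSM and the PWM stage
    at the 1 us tick.  ``angle_fn`` supplies the emulated sensor angle in
    degrees as a function of time in us (e.g. a potentiometer sweep
    fixture).  Sampling is triggered every 100 ms, the first trigger 100 ms
    after reset; the pulse-width register is initialized to the power-on
    defuzzy output and PWM width changes take effect at the next period
    boundary, never mid-pulse.
    """

    angle_fn: Callable[[int], float]
    ref: int = 70
    freq_hz: int = 50
    latency_us: int = 75
    config: FlcConfig = field(default_factory=default_flc_config)

    def run(self, horizon_us: int) -> Tuple[List[FfcSample], List[TraceEvent]]:
        pwm_cfg = PwmConfig(frequency_hz=self.freq_hz)
        reset = reset_defuzzy(self.ref, self.config)
        pulse_reg = reset.pulse
        prev_err = 0
        events: List[TraceEvent] = [
            TraceEvent(0, "defuzzy_out", reset.defuzzy),
            TraceEvent(0, "pulse_out", reset.pulse),
        ]
        samples: List[FfcSample] = []

        # pulse register timeline: (time it took effect, width)
        register_updates: List[Tuple[int, int]] = [(0, pulse_reg)]
        t = SAMPLE_PERIOD_US
        while t < horizon_us:
            events.append(TraceEvent(t, "sample", 1))
            code = angle_to_adc(self.angle_fn(t))
            acq = run_acquisition_cycle(code, self.latency_us, start_t=t)
            events.extend(acq.events)
            act_deg = adc_counts_to_degrees(acq.sample)
            conv_start = t + acq.duration_us
            events.append(TraceEvent(conv_start, "act_deg", act_deg))
            conv = run_error_conversion(self.ref, act_deg, prev_err,
                                        self.config, start_t=conv_start)
            events.extend(conv.events)
            prev_err = conv.new_prev_err
            update_t = conv_start + conv.cycles
            register_updates.append((update_t, conv.output.pulse))
            samples.append(FfcSample(
                trigger_t=t, code=code, act_deg=act_deg, err=conv.err,
                derr=conv.derr, defuzzy=conv.output.defuzzy,
                pulse=conv.output.pulse, acquisition_us=acq.duration_us,
                pulse_update_t=update_t))
            t += SAMPLE_PERIOD_US

        # PWM: at each period boundary, latch the register value in force.
        period = pwm_cfg.period_us
        ui = 0
        for p_start in range(0, horizon_us, period):
            while (ui + 1 < len(register_updates)
                   and register_updates[ui + 1][0] <= p_start):
                ui += 1
            width = register_updates[ui][1]
            events.append(TraceEvent(p_start, "pwm_out", 1))
            if p_start + width < horizon_us:
                events.append(TraceEvent(p_start + width, "pwm_out", 0))
        events.sort(key=lambda ev: ev.t)
        return samples, events
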