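"""Closed-loop coupling of the fuzzy controller and the knee plant.

The controller samples the knee angle every 100 ms.  In ``integer`` mode
the angle passes through the 8-bit converter chain (degrees -> code ->
integer degrees) and the exact fixed-point datapath; in ``float`` mode the
real-valued reference pipeline sees the angle directly.  The resulting
pulse width is held on the plant until the next sample (zero-order hold;
the 20-50 Hz pulse-train structure within a sample interval is summarized
by its width, which is what the activation stage responds to).

Step-response metrics follow the usual servo definitions: 10-90 % rise
time, 2 % settling time (last entry into the band), overshoot in degrees
above the reference, and steady-state error as the mean absolute offset
over the final second.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .flc import FlcConfig, default_flc_config, flc_step, flc_step_float, reset_defuzzy
from .fsm import adc_counts_to_degrees, angle_to_adc
from .plant import KneePlant, PlantParams, PlantState, default_plant_params

__all__ = [
    "ClosedLoopTrace",
    "StepMetrics",
    "NotSettledError",
    "simulate",
    "step_metrics",
    "compare_traces",
]

SAMPLE_PERIOD_S = 0.1


class NotSettledError(RuntimeError):
    """The trajectory does not remain inside the 2 % band at the end."""


@dataclass(frozen=True)
class StepMetrics:
    """Step-response summary of one closed-loop trajectory."""

    rise_time_s: float
    settling_time_s: float
    overshoot_deg: float
    steady_state_error_deg: float


@dataclass
class ClosedLoopTrace:
    """Controller-rate samples plus the dense plant trajectory.

    ``samples``: t, ref, act, err, derr, defuzzy, pulse at each 0.1 s
    controller instant (row 0 holds the power-on register state).
    ``dense``: t, angle, velocity, torque, pulse on the inner plant step.
    """

    samples: pd.DataFrame
    dense: pd.DataFrame
    ref: int
    mode: str


def simulate(ref: int, duration_s: float, mode: str = "integer",
             flc_config: Optional[FlcConfig] = None,
             plant_params: Optional[PlantParams] = None,
             dt: float = 1e-3,
             noise_std_deg: float = 0.0,
             rng: Optional[np.random.Generator] = None,
             pulse_override: Optional[float] = None) -> ClosedLoopTrace:
    """Run the sampled closed loop for ``duration_s`` seconds.

    ``mode`` selects the integer datapath or the real-valued reference
    pipeline.  ``pulse_override`` bypasses the controller entirely and
    drives the plant with a fixed pulse width (useful for open-loop tests).
    Optional Gaussian sensor noise (standard deviation in degrees) is added
    to the angle seen by the controller only, never to the plant state.
    """
    if mode not in ("integer", "float"):
        raise ValueError(f"mode must be 'integer' or 'float', got {mode!r}")
    if duration_s < 1.0:
        raise ValueError("duration must be at least 1 s")
    if noise_std_deg and rng is None:
        rng = np.random.default_rng(0)

    flc_config = flc_config or default_flc_config()
    plant_params = plant_params or default_plant_params()
    plant = KneePlant(params=plant_params, dt=dt)

    reset = reset_defuzzy(ref, flc_config)
    if pulse_override is not None:
        pulse: float = pulse_override
        defuzzy: float = pulse_override / flc_config.pulse_multiplier
    else:
        pulse = float(reset.pulse)
        defuzzy = float(reset.defuzzy)
    prev_err: float = 0.0

    sample_rows: List[Tuple[float, ...]] = [
        (0.0, float(ref), 0.0, 0.0, 0.0, defuzzy, pulse)]
    dense_t: List[float] = [0.0]
    dense_rows: List[Tuple[float, float, float, float]] = [
        (plant.state.angle_deg, plant.state.velocity_deg_s,
         plant.state.torque, pulse)]

    n_samples = round(duration_s / SAMPLE_PERIOD_S)
    for k in range(1, n_samples + 1):
        held_pulse = pulse

        def record(t: float, st: PlantState) -> None:
            dense_t.append(t)
            dense_rows.append((st.angle_deg, st.velocity_deg_s, st.torque,
                               held_pulse))

        plant.step(pulse, SAMPLE_PERIOD_S, record=record,
                   t0=(k - 1) * SAMPLE_PERIOD_S)
        t_k = k * SAMPLE_PERIOD_S
        theta = plant.state.angle_deg
        sensed = theta
        if noise_std_deg:
            sensed = theta + rng.normal(0.0, noise_std_deg)

        if pulse_override is not None:
            sample_rows.append((t_k, float(ref), sensed, math.nan, math.nan,
                                defuzzy, pulse))
            continue
        if mode == "integer":
            act = adc_counts_to_degrees(angle_to_adc(sensed))
            old_prev = int(prev_err)
            result, prev_err = flc_step(ref, act, old_prev, flc_config)
            err = ref - act
            derr = err - old_prev
            defuzzy = float(result.defuzzy)
            pulse = float(result.pulse)
            sample_rows.append((t_k, float(ref), float(act), float(err),
                                float(derr), defuzzy, pulse))
        else:
            act = float(sensed)
            new_err = ref - act
            dval, prev_err = flc_step_float(ref, act, prev_err, flc_config)
            defuzzy = dval
            pulse = dval * flc_config.pulse_multiplier
            sample_rows.append((t_k, float(ref), act, new_err,
                                new_err - sample_rows[-1][3], defuzzy, pulse))

    samples = pd.DataFrame(
        sample_rows,
        columns=["t", "ref", "act", "err", "derr", "defuzzy", "pulse"])
    dense = pd.DataFrame(dense_rows,
                         columns=["angle", "velocity", "torque", "pulse"])
    dense.insert(0, "t", dense_t)
    return ClosedLoopTrace(samples=samples, dense=dense, ref=ref, mode=mode)


def step_metrics(trace: ClosedLoopTrace, ref: Optional[float] = None,
                 rise_band: Tuple[float, float] = (0.1, 0.9),
                 settle_frac: float = 0.02,
                 sse_window_s: float = 1.0) -> StepMetrics:
    """Step-response metrics of a closed-loop trace (dense trajectory).

    Rise time is the first 10 % -> 90 % crossing interval; settling time is
    the last entry into the +/- 2 % band; overshoot is ``max(theta) - ref``
    clipped at zero; steady-state error is the absolute offset of the mean
    angle over the final ``sse_window_s`` seconds.  Raises
    :class:`NotSettledError` if the final fifth of the trajectory is not
    entirely inside the band.
    """
    ref = float(trace.ref if ref is None else ref)
    t = trace.dense["t"].to_numpy()
    theta = trace.dense["angle"].to_numpy()
    return _metrics_from_arrays(t, theta, ref, rise_band, settle_frac,
                                sse_window_s)


def _metrics_from_arrays(t: np.ndarray, theta: np.ndarray, ref: float,
                         rise_band: Tuple[float, float] = (0.1, 0.9),
                         settle_frac: float = 0.02,
                         sse_window_s: float = 1.0) -> StepMetrics:
    lo, hi = rise_band
    above_lo = np.nonzero(theta >= lo * ref)[0]
    above_hi = np.nonzero(theta >= hi * ref)[0]
    if len(above_lo) == 0 or len(above_hi) == 0:
        raise NotSettledError("trajectory never approaches the reference")
    rise = float(t[above_hi[0]] - t[above_lo[0]])

    band = settle_frac * ref
    inside = np.abs(theta - ref) <= band
    tail = max(1, len(theta) // 5)
    if not inside[-tail:].all():
        raise NotSettledError(
            f"final 20 % of the trajectory leaves the +/-{band:.2f} deg band")
    outside = np.nonzero(~inside)[0]
    if len(outside) == 0:
        settle = 0.0
    else:
        settle = float(t[outside[-1] + 1])

    overshoot = max(0.0, float(theta.max()) - ref)
    sse_mask = t >= t[-1] - sse_window_s
    sse = abs(ref - float(theta[sse_mask].mean()))
    return StepMetrics(rise_time_s=rise, settling_time_s=settle,
                       overshoot_deg=overshoot, steady_state_error_deg=sse)


def compare_traces(reference_vals: Sequence[float],
                   test_vals: Sequence[float],
                   ) -> Tuple[np.ndarray, float]:
    """Per-sample percentage error against a reference sequence.

    ``e_i = |ref_i - test_i| / ref_i * 100`` rounded to one decimal, plus
    the average of the rounded errors (also to one decimal).  Samples with a
    zero reference value are excluded with a warning.
    """
    ref = np.asarray(reference_vals, dtype=float)
    test = np.asarray(test_vals, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("sequences must have equal length")
    nonzero = ref != 0
    if not nonzero.all():
        warnings.warn(
            f"excluding {int((~nonzero).sum())} sample(s) with zero "
            "reference value", stacklevel=2)
    ref = ref[nonzero]
    test = test[nonzero]
    if ref.size == 0:
        raise ValueError("no nonzero reference samples to compare")
    errors = np.round(np.abs(ref - test) / ref * 100.0, 1)
    return errors, float(np.round(errors.mean(), 1))
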