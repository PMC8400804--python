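"""Trace I/O and synthetic sensor fixtures.

Traces are plain CSV with a header row; integer signal columns survive a
write/read round trip bit-exactly, float columns to full double precision.
The sweep fixture emulates the bench test in which a rotary potentiometer
standing in for the knee is turned from 0 to 90 degrees and held: a
piecewise-linear ramp sampled on the 100 ms controller grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["TraceParseError", "write_trace", "read_trace",
           "SweepFixture", "generate_ramp_sweep"]


class TraceParseError(ValueError):
    """A trace file could not be parsed; the message carries the location."""


def write_trace(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trace DataFrame as CSV (header always included)."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trace CSV; malformed input raises :class:`TraceParseError`."""
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TraceParseError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"{path}: file is empty (no header)") from exc


@dataclass(frozen=True)
class SweepFixture:
    """Emulated potentiometer sweep: angles on the 100 ms sample grid."""

    times_s: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg > 90):
            raise ValueError("sweep angles must lie in [0, 90] degrees")
        if np.any(np.diff(self.angles_deg) < -1e-12):
            raise ValueError("sweep must be non-decreasing")

    def angle_at(self, t_s: float) -> float:
        """Sample-and-hold lookup of the swept angle at time ``t_s``."""
        idx = int(np.searchsorted(self.times_s, t_s, side="right")) - 1
        idx = max(0, min(idx, len(self.angles_deg) - 1))
        return float(self.angles_deg[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times_s, "angle": self.angles_deg})


def generate_ramp_sweep(ramp_duration_s: float | None = 0.9,
                        hold_s: float = 0.5,
                        rate_deg_s: float | None = None,
                        sample_period_s: float = 0.1) -> SweepFixture:
    """Piecewise-linear 0 -> 90 degree ramp followed by a hold segment.

    Either the ramp duration or the ramp rate (deg/s) may be given; the
    fixture is sampled on the controller grid (100 ms by default).  A ramp
    of 0.9 s yields the samples 0, 10, ..., 90.
    """
    if rate_deg_s is not None:
        if rate_deg_s <= 0:
            raise ValueError("ramp rate must be positive")
        ramp_duration_s = 90.0 / rate_deg_s
    if ramp_duration_s is None or ramp_duration_s <= 0 or hold_s <= 0:
        raise ValueError("durations must be positive")
    total = ramp_duration_s + hold_s
    n = int(round(total / sample_period_s))
    t = np.arange(n + 1) * sample_period_s
    angles = np.minimum(90.0, t * (90.0 / ramp_duration_s))
    return SweepFixture(times_s=t, angles_deg=angles)
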