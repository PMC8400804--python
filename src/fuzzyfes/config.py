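"""Configuration loading, validation and serialization.

A run configuration bundles the dip-switch codes (reference angle and
stimulation frequency), the full controller parameterization, the plant
parameters and the simulation settings.  Configurations round-trip through
YAML; membership breakpoints and singleton positions may be written either
as decimal integers or as hexadecimal strings ("$7F" or "0x7F"), matching
the notation used in digital design documents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Union

import yaml

from .flc import (FlcConfig, FuzzyConfigError, IN_LABELS, OUT_LABELS,
                  RULE_OUTPUT, SingletonTable, TriangleParams,
                  default_flc_config)
from .plant import PlantParams, default_plant_params

__all__ = ["RunConfig", "default_run_config", "load_config", "dump_config",
           "config_to_dict", "config_from_dict"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    ref_set: int = 0b00          # 2-bit code: 00->70, 01->40, 10->30
    freq_sel: int = 0b11         # 2-bit code: 00->20 ... 11->50 Hz
    flc: FlcConfig = field(default_factory=default_flc_config)
    plant: PlantParams = field(default_factory=default_plant_params)
    horizon_s: float = 8.0
    device_latency_us: int = 75
    noise_std_deg: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ref_set not in (0, 1, 2, 3) or self.freq_sel not in (0, 1, 2, 3):
            raise ValueError("ref_set and freq_sel must be 2-bit codes")
        if self.horizon_s <= 0:
            raise ValueError("horizon must be positive")
        if self.noise_std_deg < 0:
            raise ValueError("noise std must be >= 0")


def default_run_config() -> RunConfig:
    return RunConfig()


def _parse_byte(v: Union[int, str]) -> int:
    """Accept a decimal int or a '$7F' / '0x7F' hexadecimal string."""
    if isinstance(v, int):
        return v
    s = str(v).strip()
    if s.startswith("$"):
        return int(s[1:], 16)
    return int(s, 0)


def config_to_dict(cfg: RunConfig) -> Dict[str, Any]:
    return {
        "ref_set": cfg.ref_set,
        "freq_sel": cfg.freq_sel,
        "flc": {
            "clamp_deg": cfg.flc.clamp_deg,
            "pulse_multiplier": cfg.flc.pulse_multiplier,
            "memberships": {
                label: list(t)
                for label, t in zip(IN_LABELS, cfg.flc.memberships)
            },
            "rules": list(cfg.flc.rules),
            "singletons": {
                int(ref): {lab: getattr(tab, lab) for lab in OUT_LABELS}
                for ref, tab in sorted(cfg.flc.singletons.items())
            },
        },
        "plant": dataclasses.asdict(cfg.plant),
        "horizon_s": cfg.horizon_s,
        "device_latency_us": cfg.device_latency_us,
        "noise_std_deg": cfg.noise_std_deg,
        "seed": cfg.seed,
    }


def config_from_dict(d: Mapping[str, Any]) -> RunConfig:
    flc_d = d.get("flc", {})
    memberships = flc_d.get("memberships")
    if memberships is None:
        mfs = default_flc_config().memberships
    else:
        try:
            mfs = tuple(
                TriangleParams(*(_parse_byte(v) for v in memberships[label]))
                for label in IN_LABELS)
        except KeyError as exc:
            raise FuzzyConfigError(f"missing membership set {exc}") from None
    singles_d = flc_d.get("singletons")
    if singles_d is None:
        singletons = default_flc_config().singletons
    else:
        singletons = {
            int(ref): SingletonTable(
                **{lab: _parse_byte(tab[lab]) for lab in OUT_LABELS},
                reference_angle=int(ref))
            for ref, tab in singles_d.items()
        }
    flc = FlcConfig(
        memberships=mfs,
        rules=tuple(flc_d.get("rules", RULE_OUTPUT)),
        singletons=singletons,
        pulse_multiplier=int(flc_d.get("pulse_multiplier", 10)),
        clamp_deg=int(flc_d.get("clamp_deg", 20)),
    )
    plant_d = dict(d.get("plant", {}))
    plant = PlantParams(**plant_d) if plant_d else default_plant_params()
    return RunConfig(
        ref_set=int(d.get("ref_set", 0)),
        freq_sel=int(d.get("freq_sel", 3)),
        flc=flc,
        plant=plant,
        horizon_s=float(d.get("horizon_s", 8.0)),
        device_latency_us=int(d.get("device_latency_us", 75)),
        noise_std_deg=float(d.get("noise_std_deg", 0.0)),
        seed=d.get("seed"),
    )


def dump_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path: Union[str, Path]) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} does not hold a mapping")
    return config_from_dict(data)
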