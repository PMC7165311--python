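"""Simulation protocols: the structured description of a fall re-enactment.

A protocol is an ordered list of phase specifications (label, duration and
kinematic parameters) together with sensor settings (sampling rate, noise
level, optional clipping range) and a seed.  Protocols are plain data: the
simulator turns them into signals, and they serialize losslessly to a small
YAML/JSON mapping (see :mod:`fallwarp.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Sequence

from .signals import PHASE_NAMES

#: Phase kind implied by each label.
PHASE_KIND = {1: "steps", 2: "fall_impact", 3: "rest", 4: "raise", 5: "rest", 6: "stand"}

#: Required kinematic parameters per phase kind.
REQUIRED_PARAMS = {
    "steps": ("step_frequency_hz", "step_amplitude_g"),
    "fall_impact": ("freefall_duration_s", "impact_peak_g", "impact_duration_s", "end_pitch_deg"),
    "rest": ("pitch_deg",),
    "raise": ("start_pitch_deg", "end_pitch_deg", "transient_amplitude_g"),
    "stand": ("start_pitch_deg", "end_pitch_deg", "transient_amplitude_g"),
}

_PITCH_PARAMS = ("pitch_deg", "end_pitch_deg", "start_pitch_deg")


@dataclass(frozen=True)
class PhaseSpec:
    """One phase of a re-enactment protocol.

    ``label`` (1..6) fixes both the phase meaning and the required ``params``
    keys; pitch angles are trunk pitch in degrees (0 = upright, 90 =
    horizontal forward bend) and must lie in [-180, 180].
    """

    label: int
    duration_s: float
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in PHASE_NAMES:
            raise ValueError(f"unknown phase label {self.label}; expected 1..6")
        if self.duration_s < 0:
            raise ValueError(f"phase {self.label} duration must be >= 0, got {self.duration_s}")
        kind = PHASE_KIND[self.label]
        required = REQUIRED_PARAMS[kind]
        params = dict(self.params)
        missing = [k for k in required if k not in params]
        if missing:
            raise ValueError(f"phase {self.label} ({kind}) missing params: {missing}")
        unknown = [k for k in params if k not in required]
        if unknown:
            raise ValueError(f"phase {self.label} ({kind}) has unknown params: {unknown}")
        for key in _PITCH_PARAMS:
            if key in params and not (-180.0 <= float(params[key]) <= 180.0):
                raise ValueError(f"{key}={params[key]} outside [-180, 180] degrees")
        object.__setattr__(self, "params", params)

    @property
    def kind(self) -> str:
        return PHASE_KIND[self.label]

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "duration_s": float(self.duration_s),
            "params": {k: float(v) for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PhaseSpec":
        unknown = set(d) - {"label", "duration_s", "params"}
        if unknown:
            raise ValueError(f"unknown phase keys: {sorted(unknown)}")
        if "label" not in d or "duration_s" not in d:
            raise ValueError("phase entry requires 'label' and 'duration_s'")
        return cls(
            label=int(d["label"]),
            duration_s=float(d["duration_s"]),
            params=dict(d.get("params", {})),
        )


@dataclass(frozen=True)
class SimulationProtocol:
    """Ordered phase specifications plus sensor-noise settings and seed."""

    phases: Sequence[PhaseSpec]
    sampling_rate_hz: float = 100.0
    noise_sd_g: float = 0.0
    clip_range_g: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))
        if not self.sampling_rate_hz > 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if self.noise_sd_g < 0:
            raise ValueError(f"noise_sd_g must be >= 0, got {self.noise_sd_g}")
        if self.clip_range_g is not None and not self.clip_range_g > 0:
            raise ValueError(f"clip_range_g must be positive or None, got {self.clip_range_g}")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "sampling_rate_hz": float(self.sampling_rate_hz),
            "noise_sd_g": float(self.noise_sd_g),
            "seed": int(self.seed),
            "phases": [p.to_dict() for p in self.phases],
        }
        if self.clip_range_g is not None:
            d["clip_range_g"] = float(self.clip_range_g)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationProtocol":
        allowed = {"sampling_rate_hz", "noise_sd_g", "clip_range_g", "seed", "phases"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
        phases_raw = d.get("phases", [])
        if not isinstance(phases_raw, (list, tuple)):
            raise ValueError("'phases' must be a list of phase entries")
        clip = d.get("clip_range_g")
        return cls(
            phases=[PhaseSpec.from_dict(p) for p in phases_raw],
            sampling_rate_hz=float(d.get("sampling_rate_hz", 100.0)),
            noise_sd_g=float(d.get("noise_sd_g", 0.0)),
            clip_range_g=None if clip is None else float(clip),
            seed=int(d.get("seed", 0)),
        )

    def with_seed(self, seed: int) -> "SimulationProtocol":
        return replace(self, seed=int(seed))
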