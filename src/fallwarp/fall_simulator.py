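"""Synthetic six-phase fall-signal generator.

Emulates the triaxial acceleration signature of a forward fall recorded by
a smartphone accelerometer worn at the lower back (L5), close to the
trunk's center of mass: prefall steps, stumble/fall/impact, resting on the
ground, raising the upper body, resting on the knees, and straightening up
to standing.  The kinematic model is a single-angle (trunk pitch) rigid-body
approximation: in a static posture with pitch theta (0 deg = upright,
90 deg = horizontal forward bend), gravity reads

    z = cos(theta) g (vertical),  x = sin(theta) g (sagittal),  y = 0,

so the noise-free static magnitude is exactly 1 g.  Roll and yaw are out of
scope.  The impact transient is synthetic — a half-sine burst — since real
ground impacts depend on surface properties the model does not represent.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .protocol import PhaseSpec, SimulationProtocol
from .signals import PhaseAnnotation, TriaxialAccelerationSignal

#: Fixed oscillation frequency (Hz) of the decaying transient superimposed
#: on raising / standing-up phases.
TRANSIENT_FREQUENCY_HZ = 3.0


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (deterministic)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _gravity(pitch_deg: float) -> tuple[float, float, float]:
    theta = math.radians(pitch_deg)
    return math.sin(theta), 0.0, math.cos(theta)


def _phase_waveform(phase: PhaseSpec, n: int, rate: float) -> np.ndarray:
    """Noise-free (n, 3) waveform for one phase, local time starting at 0."""
    out = np.zeros((n, 3))
    if n == 0:
        return out
    t = np.arange(n) / rate
    p = phase.params
    kind = phase.kind

    if kind == "steps":
        f = p["step_frequency_hz"]
        amp = p["step_amplitude_g"]
        out[:, 2] = 1.0 + amp * np.sin(2 * np.pi * f * t)
        # mediolateral sway alternates with each step, i.e. at half the
        # step frequency, with a quarter of the vertical amplitude
        out[:, 1] = (amp / 4.0) * np.sin(2 * np.pi * (f / 2.0) * t)

    elif kind == "fall_impact":
        t_ff = p["freefall_duration_s"]
        t_imp = p["impact_duration_s"]
        peak = p["impact_peak_g"]
        gx, gy, gz = _gravity(p["end_pitch_deg"])
        # 1) free fall: total magnitude decays from 1 g toward 0
        in_ff = t < t_ff
        if t_ff > 0:
            out[in_ff, 2] = 1.0 - t[in_ff] / t_ff
        # 2) impact: half-sine transient on the vertical and sagittal axes
        in_imp = (t >= t_ff) & (t < t_ff + t_imp)
        if t_imp > 0:
            s = (t[in_imp] - t_ff) / t_imp
            burst = peak * np.sin(np.pi * s)
            out[in_imp, 2] = burst
            out[in_imp, 0] = burst
        # 3) settle into the static reading at the end pitch
        after = t >= t_ff + t_imp
        out[after, 0] = gx
        out[after, 1] = gy
        out[after, 2] = gz

    elif kind == "rest":
        gx, gy, gz = _gravity(p["pitch_deg"])
        out[:, 0] = gx
        out[:, 1] = gy
        out[:, 2] = gz

    elif kind in ("raise", "stand"):
        th0 = p["start_pitch_deg"]
        th1 = p["end_pitch_deg"]
        amp = p["transient_amplitude_g"]
        duration = n / rate
        # smooth cosine ramp of the trunk pitch from start to end
        frac = (1.0 - np.cos(np.pi * t / duration)) / 2.0 if duration > 0 else t * 0
        theta = np.radians(th0 + (th1 - th0) * frac)
        out[:, 0] = np.sin(theta)
        out[:, 2] = np.cos(theta)
        # movement transient, linearly decaying to zero by phase end
        envelope = amp * (1.0 - t / duration) if duration > 0 else t * 0
        out[:, 2] += envelope * np.sin(2 * np.pi * TRANSIENT_FREQUENCY_HZ * t)

    else:  # pragma: no cover - PhaseSpec validation forbids this
        raise ValueError(f"unknown phase kind {kind!r}")
    return out


def simulate_fall(
    protocol: SimulationProtocol,
) -> tuple[TriaxialAccelerationSignal, list[PhaseAnnotation]]:
    """Generate a synthetic fall signal and its ground-truth annotations.

    Phase segments are concatenated in protocol order; each spans
    ``round(duration_s * rate)`` samples (halves away from zero) and the
    annotations tile the concatenation exactly (zero-length phases emit no
    annotation).  Per-axis i.i.d. Gaussian noise of ``noise_sd_g`` is drawn
    from per-phase substreams derived deterministically from the protocol
    seed, so the same protocol and seed always reproduce the identical
    signal bit for bit, even when other phases are edited.
    """
    rate = protocol.sampling_rate_hz
    streams = np.random.SeedSequence(protocol.seed).spawn(max(len(protocol.phases), 1))
    segments: list[np.ndarray] = []
    annotations: list[PhaseAnnotation] = []
    cursor = 0
    for phase, stream in zip(protocol.phases, streams):
        n = _round_half_away(phase.duration_s * rate)
        block = _phase_waveform(phase, n, rate)
        if protocol.noise_sd_g > 0 and n > 0:
            rng = np.random.default_rng(stream)
            block = block + rng.normal(0.0, protocol.noise_sd_g, size=(n, 3))
        segments.append(block)
        if n > 0:
            annotations.append(PhaseAnnotation(phase.label, cursor, cursor + n))
        cursor += n
    data = np.vstack(segments) if segments else np.zeros((0, 3))
    if protocol.clip_range_g is not None:
        data = np.clip(data, -protocol.clip_range_g, protocol.clip_range_g)
    signal = TriaxialAccelerationSignal(data=data, sampling_rate_hz=rate)
    return signal, annotations


def default_protocol(seed: int = 0) -> SimulationProtocol:
    """Demonstration protocol for a forward fall onto the knees.

    The six phases mirror a common real-world fall paradigm — stumbling
    over a door sill, falling forward on the knees, touching the ground
    with the hands for 1.5 s, sudden raising, 4 s of resting on the knees
    with the upper body upright, then standing up.  The ground-contact
    (1.5 s, within the protocol's 1–2 s instruction) and kneeling-rest
    (4 s) durations follow the written re-enactment instructions; the
    remaining durations, pitches and amplitudes are package defaults chosen
    to produce a plausible lower-back acceleration trace.
    """
    phases = [
        PhaseSpec(1, 5.0, {"step_frequency_hz": 2.0, "step_amplitude_g": 0.15}),
        PhaseSpec(
            2,
            1.5,
            {
                "freefall_duration_s": 0.35,
                "impact_peak_g": 3.0,
                "impact_duration_s": 0.12,
                "end_pitch_deg": 75.0,
            },
        ),
        PhaseSpec(3, 1.5, {"pitch_deg": 75.0}),
        PhaseSpec(
            4,
            1.2,
            {"start_pitch_deg": 75.0, "end_pitch_deg": 10.0, "transient_amplitude_g": 0.25},
        ),
        PhaseSpec(5, 4.0, {"pitch_deg": 10.0}),
        PhaseSpec(
            6,
            2.5,
            {"start_pitch_deg": 10.0, "end_pitch_deg": 0.0, "transient_amplitude_g": 0.2},
        ),
    ]
    return SimulationProtocol(
        phases=phases, sampling_rate_hz=100.0, noise_sd_g=0.02, clip_range_g=None, seed=seed
    )


#: Parameters scaled multiplicatively by :func:`perturb_protocol`.
_SCALED_PARAMS = (
    "step_frequency_hz",
    "step_amplitude_g",
    "impact_peak_g",
    "transient_amplitude_g",
)


def perturb_protocol(
    protocol: SimulationProtocol,
    duration_deltas_s: Sequence[float],
    param_scale: float,
    seed: int,
) -> SimulationProtocol:
    """Derive a new re-enactment iteration by perturbing a protocol.

    ``duration_deltas_s`` (one entry per phase) is added to each phase's
    duration; phases with a positive original duration are clamped at a
    minimum of 0.1 s.  Amplitude and frequency parameters are multiplied by
    independent factors drawn uniformly from ``[1 - param_scale,
    1 + param_scale]`` using the given seed.  Zero deltas with
    ``param_scale = 0`` return an identical protocol.
    """
    if param_scale < 0:
        raise ValueError(f"param_scale must be >= 0, got {param_scale}")
    deltas = list(duration_deltas_s)
    if len(deltas) != len(protocol.phases):
        raise ValueError(
            f"expected {len(protocol.phases)} duration deltas, got {len(deltas)}"
        )
    rng = np.random.default_rng(seed)
    new_phases = []
    for phase, delta in zip(protocol.phases, deltas):
        duration = phase.duration_s + float(delta)
        if phase.duration_s > 0:
            # clamp at 0.1 s (never above the original, so zero deltas are exact)
            duration = max(duration, min(0.1, phase.duration_s))
        else:
            duration = max(duration, 0.0)
        params = dict(phase.params)
        for key in _SCALED_PARAMS:
            if key in params:
                factor = rng.uniform(1.0 - param_scale, 1.0 + param_scale)
                params[key] = params[key] * factor
        new_phases.append(PhaseSpec(phase.label, duration, params))
    return SimulationProtocol(
        phases=new_phases,
        sampling_rate_hz=protocol.sampling_rate_hz,
        noise_sd_g=protocol.noise_sd_g,
        clip_range_g=protocol.clip_range_g,
        seed=protocol.seed,
    )
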