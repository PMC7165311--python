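"""Reading, writing and resampling of signals, protocols and annotations.

File formats
------------
Signal CSV
    Header ``time,x,y,z``; time in seconds on a uniform grid; x/y/z in g.
    Comma separator, dot decimal, UTF-8.  Floats are written with ``%.17g``
    so write -> read -> write is byte-identical.
Protocol config (YAML, JSON-compatible subset)
    Mapping with keys ``sampling_rate_hz``, ``noise_sd_g``, ``seed``,
    optional ``clip_range_g`` and ``phases`` — a list of
    ``{label, duration_s, params}`` entries.  Unknown keys are rejected.
Annotation CSV
    Header ``label,start_index,end_index`` with 0-based half-open intervals.
"""

from __future__ import annotations

import io
import math
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .protocol import SimulationProtocol
from .signals import PhaseAnnotation, TriaxialAccelerationSignal, validate_annotations

PathLike = Union[str, Path]

#: Maximum allowed deviation of any inter-sample gap from the median gap,
#: as a fraction of the median gap (phone logs jitter slightly).
GRID_TOLERANCE = 0.01

_SIGNAL_COLUMNS = ("time", "x", "y", "z")


def _check_uniform_grid(times: np.ndarray) -> float:
    """Return the median inter-sample gap, rejecting non-uniform grids."""
    gaps = np.diff(times)
    median = float(np.median(gaps))
    if median <= 0:
        raise ValueError("timestamps must be strictly increasing")
    if np.max(np.abs(gaps - median)) > GRID_TOLERANCE * median:
        raise ValueError(
            "non-uniform sample grid: an inter-sample gap deviates from the "
            f"median gap {median:g} s by more than {GRID_TOLERANCE:.0%}"
        )
    return median


def read_signal_csv(
    path: PathLike, sampling_rate_hz: Union[float, str] = "infer"
) -> TriaxialAccelerationSignal:
    """Read a triaxial signal from a ``time,x,y,z`` CSV file.

    Parameters
    ----------
    path
        CSV file with a header row naming columns time, x, y, z
        (case-insensitive) and numeric body rows.
    sampling_rate_hz
        Either a positive rate in Hz, or ``"infer"`` to derive the rate as
        the reciprocal of the median inter-row time difference (requires at
        least 2 rows).

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file, missing/renamed columns, non-numeric cells,
        non-uniform timestamps, or inference with fewer than 2 rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such signal file: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in _SIGNAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    frame = frame[list(_SIGNAL_COLUMNS)]
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in signal body: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError(f"{path}: non-numeric or empty cell in signal body")

    times = values[:, 0]
    if isinstance(sampling_rate_hz, str):
        if sampling_rate_hz != "infer":
            raise ValueError(f"sampling_rate_hz must be positive or 'infer', got {sampling_rate_hz!r}")
        if len(times) < 2:
            raise ValueError(f"{path}: cannot infer sampling rate from fewer than 2 rows")
        rate = 1.0 / _check_uniform_grid(times)
    else:
        rate = float(sampling_rate_hz)
        if rate <= 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {rate}")
        if len(times) >= 2:
            _check_uniform_grid(times)
    start = float(times[0]) if len(times) else 0.0
    return TriaxialAccelerationSignal(
        data=values[:, 1:4], sampling_rate_hz=rate, start_time_s=start
    )


def write_signal_csv(signal: TriaxialAccelerationSignal, path: PathLike) -> None:
    """Write a signal as a ``time,x,y,z`` CSV with round-trip-safe precision."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("time,x,y,z\n")
    times = signal.times
    for i in range(signal.n_samples):
        x, y, z = signal.data[i]
        buf.write(f"{times[i]:.17g},{x:.17g},{y:.17g},{z:.17g}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def resample(
    signal: TriaxialAccelerationSignal, target_hz: float
) -> TriaxialAccelerationSignal:
    """Linearly resample a signal onto a new uniform grid at ``target_hz``.

    The new grid starts at the signal's start time and spans the same time
    range; a trailing partial interval is dropped.  Requires >= 2 samples.
    """
    if target_hz <= 0:
        raise ValueError(f"target rate must be > 0, got {target_hz}")
    if signal.n_samples < 2:
        raise ValueError("resampling requires at least 2 samples")
    if target_hz == signal.sampling_rate_hz:
        return TriaxialAccelerationSignal(
            data=signal.data.copy(),
            sampling_rate_hz=signal.sampling_rate_hz,
            start_time_s=signal.start_time_s,
        )
    span = (signal.n_samples - 1) / signal.sampling_rate_hz
    # includes the endpoint when it lands on the new grid (within float slack)
    n_new = int(math.floor(span * target_hz + 1e-9)) + 1
    old_t = signal.times
    new_t = signal.start_time_s + np.arange(n_new) / target_hz
    data = np.column_stack(
        [np.interp(new_t, old_t, signal.data[:, k]) for k in range(3)]
    )
    return TriaxialAccelerationSignal(
        data=data, sampling_rate_hz=float(target_hz), start_time_s=signal.start_time_s
    )


# -- protocols ----------------------------------------------------------


def load_protocol(path: PathLike) -> SimulationProtocol:
    """Load and validate a simulation protocol from a YAML/JSON config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such protocol file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: protocol file must contain a mapping")
    return SimulationProtocol.from_dict(raw)


def save_protocol(protocol: SimulationProtocol, path: PathLike) -> None:
    """Write a protocol to a YAML config file (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(protocol.to_dict(), fh, sort_keys=False)


# -- annotations --------------------------------------------------------


def write_annotations_csv(
    annotations: Sequence[PhaseAnnotation], path: PathLike
) -> None:
    """Write phase annotations as ``label,start_index,end_index`` CSV."""
    lines = ["label,start_index,end_index"]
    lines += [f"{a.label},{a.start_index},{a.end_index}" for a in annotations]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotations_csv(
    path: PathLike, n_samples: int | None = None
) -> list[PhaseAnnotation]:
    """Read phase annotations; validates ordering (and bounds if given)."""
    frame = pd.read_csv(path)
    anns = [
        PhaseAnnotation(int(r.label), int(r.start_index), int(r.end_index))
        for r in frame.itertuples()
    ]
    if n_samples is not None:
        validate_annotations(anns, n_samples)
    return anns
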