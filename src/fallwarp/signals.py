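"""Core signal containers for triaxial trunk accelerometry.

A recording is a uniformly sampled series of (x, y, z) acceleration triples
in units of g, following the lower-back sensor convention used in wearable
fall research: z vertical, y mediolateral, x sagittal.  Fall events are
described by phase annotations over the sample grid, labelled 1..6:

1. prefall phase with steps
2. stumbling, falling, and impact
3. resting
4. raising the upper body
5. resting
6. straightening up into a standing position
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Fixed axis meaning for a lower-back (L5) worn sensor.
AXIS_CONVENTION = {"x": "sagittal", "y": "mediolateral", "z": "vertical"}

#: Column index of each axis in the sample array.
AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: Human-readable names of the six fall phases.
PHASE_NAMES = {
    1: "prefall steps",
    2: "stumble/fall/impact",
    3: "resting",
    4: "raising upper body",
    5: "resting",
    6: "straighten up to standing",
}


@dataclass
class TriaxialAccelerationSignal:
    """Uniformly sampled 3-axis acceleration series.

    Parameters
    ----------
    data
        Array of shape (n, 3) holding (x, y, z) acceleration in g.
    sampling_rate_hz
        Sampling rate in Hz; must be positive.
    start_time_s
        Time of the first sample in seconds (default 0); sample ``i`` sits at
        ``start_time_s + i / sampling_rate_hz``.
    """

    data: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    axis_convention: dict = field(default_factory=lambda: dict(AXIS_CONVENTION))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.size == 0:
            self.data = self.data.reshape(0, 3)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError(
                f"signal data must have shape (n, 3), got {self.data.shape}"
            )
        if not self.sampling_rate_hz > 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("acceleration values must all be finite")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def __len__(self) -> int:
        return self.n_samples

    @property
    def duration_s(self) -> float:
        """Time span covered by the sample grid (0 for empty signals)."""
        if self.n_samples == 0:
            return 0.0
        return (self.n_samples - 1) / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Timestamps of every sample on the uniform grid, in seconds."""
        return self.start_time_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def axis(self, name: str) -> np.ndarray:
        """Return one axis (``"x"``, ``"y"`` or ``"z"``) as a 1-D array."""
        try:
            return self.data[:, AXIS_INDEX[name]]
        except KeyError:
            raise ValueError(f"unknown axis {name!r}; expected one of x, y, z") from None

    def equals(self, other: "TriaxialAccelerationSignal") -> bool:
        """Field-by-field equality (exact float comparison)."""
        return (
            self.sampling_rate_hz == other.sampling_rate_hz
            and self.start_time_s == other.start_time_s
            and self.data.shape == other.data.shape
            and bool(np.all(self.data == other.data))
        )


@dataclass(frozen=True)
class PhaseAnnotation:
    """Half-open sample-index interval ``[start_index, end_index)`` with a
    fall-phase label in 1..6."""

    label: int
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.label not in PHASE_NAMES:
            raise ValueError(f"phase label must be in 1..6, got {self.label}")
        if not (0 <= self.start_index < self.end_index):
            raise ValueError(
                f"annotation requires 0 <= start < end, got "
                f"[{self.start_index}, {self.end_index})"
            )

    def duration_s(self, sampling_rate_hz: float) -> float:
        return (self.end_index - self.start_index) / sampling_rate_hz


def validate_annotations(
    annotations: Iterable[PhaseAnnotation], n_samples: int
) -> list[PhaseAnnotation]:
    """Check that annotations are sorted, non-overlapping and in-bounds.

    Returns the annotations as a list, or raises ``ValueError``.
    """
    anns = list(annotations)
    prev_end = 0
    for a in anns:
        if a.start_index < prev_end:
            raise ValueError(
                f"annotations overlap or are unsorted at [{a.start_index}, {a.end_index})"
            )
        if a.end_index > n_samples:
            raise ValueError(
                f"annotation [{a.start_index}, {a.end_index}) exceeds signal "
                f"length {n_samples}"
            )
        prev_end = a.end_index
    return anns
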