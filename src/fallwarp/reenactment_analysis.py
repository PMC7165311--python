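"""The re-enactment validation workflow.

A real-world fall signal (the *reference*, used as the DTW query) is
compared per axis against one or more re-enacted signals (the *templates*).
Each iteration of the re-enactment loop yields three query-normalized
distances (x, y, z); successive iterations are summarized by their percent
improvement, and phase annotations can be transferred across the warping
path to link movement sequences between the two recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dtw_core import AlignmentResult, align_axis
from .signals import PhaseAnnotation, TriaxialAccelerationSignal, validate_annotations

AXES = ("x", "y", "z")


class PhaseTransferError(ValueError):
    """A phase boundary falls outside the matched range of the alignment."""


@dataclass
class ComparisonReport:
    """Per-axis normalized distances across re-enactment iterations.

    ``improvements[k]`` holds, per axis, ``100 * (a - b) / a`` between
    iteration k and k+1 (positive = improvement; ``None`` when the earlier
    distance is zero).  ``best_iteration`` is the iteration with the lowest
    mean per-axis distance, earliest on ties.
    """

    iterations: list[tuple[int, dict[str, float]]]
    improvements: list[dict[str, Optional[float]]]
    best_iteration: int

    def to_json_dict(self) -> dict:
        return {
            "iterations": [
                {"iteration": i, "normalized_distance": d} for i, d in self.iterations
            ],
            "improvements_percent": self.improvements,
            "best_iteration": self.best_iteration,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")


def percent_improvement(previous: float, current: float) -> Optional[float]:
    """Percent change ``100 * (previous - current) / previous``.

    Positive values mean the distance decreased.  Undefined (``None``) when
    the previous distance is zero.
    """
    if previous == 0:
        return None
    if current == previous:
        return 0.0
    # algebraically 100 * (previous - current) / previous, written so that
    # exact ratios (e.g. 2.0 -> 1.4) come out exact in floating point
    return 100.0 - 100.0 * current / previous


def compare_axes(
    reference: TriaxialAccelerationSignal,
    reenacted: TriaxialAccelerationSignal,
    open_begin: bool = True,
    open_end: bool = True,
) -> dict[str, float]:
    """Per-axis normalized DTW distances, reference as query."""
    return {
        axis: align_axis(
            reference, reenacted, axis, open_begin=open_begin, open_end=open_end
        ).normalized_distance
        for axis in AXES
    }


def iteration_report(
    reference: TriaxialAccelerationSignal,
    reenactments: Sequence[TriaxialAccelerationSignal],
    open_begin: bool = True,
    open_end: bool = True,
) -> ComparisonReport:
    """Compare every re-enactment iteration against the reference.

    Iterations are numbered from 1 in list order; improvements are computed
    per axis between consecutive iterations.
    """
    if len(reenactments) == 0:
        raise ValueError("at least one re-enactment signal is required")
    iterations = [
        (k + 1, compare_axes(reference, sig, open_begin, open_end))
        for k, sig in enumerate(reenactments)
    ]
    improvements = [
        {
            axis: percent_improvement(prev[axis], curr[axis])
            for axis in AXES
        }
        for (_, prev), (_, curr) in zip(iterations, iterations[1:])
    ]
    means = [float(np.mean([d[a] for a in AXES])) for _, d in iterations]
    best_iteration = iterations[int(np.argmin(means))][0]
    return ComparisonReport(iterations, improvements, best_iteration)


def phase_summary(
    signal: TriaxialAccelerationSignal, annotations: Sequence[PhaseAnnotation]
) -> pd.DataFrame:
    """Per-phase durations and per-axis extrema.

    Returns a DataFrame with one row per annotation: label, duration_s and
    min/max of each axis over the spanned samples.
    """
    validate_annotations(annotations, signal.n_samples)
    rows = []
    for a in annotations:
        block = signal.data[a.start_index : a.end_index]
        rows.append(
            {
                "label": a.label,
                "duration_s": a.duration_s(signal.sampling_rate_hz),
                "x_min": block[:, 0].min(),
                "x_max": block[:, 0].max(),
                "y_min": block[:, 1].min(),
                "y_max": block[:, 1].max(),
                "z_min": block[:, 2].min(),
                "z_max": block[:, 2].max(),
            }
        )
    columns = ["label", "duration_s", "x_min", "x_max", "y_min", "y_max", "z_min", "z_max"]
    return pd.DataFrame(rows, columns=columns)


def transfer_phases(
    annotations: Sequence[PhaseAnnotation],
    result: AlignmentResult,
    direction: str = "query_to_template",
) -> list[PhaseAnnotation]:
    """Map phase boundaries across the warping path.

    A start boundary maps through the first path pair matching it, an end
    boundary (exclusive, so its last contained index) through the last pair;
    where a many-to-one warp makes consecutive phases touch the same
    destination sample, the later phase is nudged forward so the output
    stays sorted and non-overlapping.

    Raises
    ------
    PhaseTransferError
        When a boundary lies outside the matched range (possible with open
        begin/end), naming every offending annotation.
    """
    if direction == "query_to_template":
        pairs = result.path
    elif direction == "template_to_query":
        pairs = [(tj, qi) for (qi, tj) in result.path]
    else:
        raise ValueError(f"unknown direction {direction!r}")

    first: dict[int, int] = {}
    last: dict[int, int] = {}
    for src, dst in pairs:
        first.setdefault(src, dst)
        last[src] = dst

    out_of_range = [
        a
        for a in annotations
        if a.start_index not in first or (a.end_index - 1) not in last
    ]
    if out_of_range:
        detail = ", ".join(
            f"phase {a.label} [{a.start_index}, {a.end_index})" for a in out_of_range
        )
        raise PhaseTransferError(
            f"boundaries outside the matched range of the alignment: {detail}"
        )

    transferred: list[PhaseAnnotation] = []
    prev_end = 0
    for a in annotations:
        start = max(first[a.start_index], prev_end)
        end = max(last[a.end_index - 1] + 1, start + 1)
        transferred.append(PhaseAnnotation(a.label, start, end))
        prev_end = end
    return transferred


def plot_alignment(
    query: np.ndarray,
    template: np.ndarray,
    result: AlignmentResult,
    out_prefix: Union[str, Path],
    axis_name: str = "z",
) -> list[Path]:
    """Write an overlay plot (query vs warped template) and a warping-path
    plot as PNG files; returns the created paths.  Advisory output only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .dtw_core import warp_template

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    created = []

    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(np.asarray(query), label="query (reference)", lw=1.0)
    ax.plot(warp_template(template, result), label="template, warped", lw=1.0)
    ax.set_xlabel("query sample")
    ax.set_ylabel(f"{axis_name} acceleration (g)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    overlay = out_prefix.with_name(out_prefix.name + f"_overlay_{axis_name}.png")
    fig.savefig(overlay, dpi=110)
    plt.close(fig)
    created.append(overlay)

    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    qp = [p[0] for p in result.path]
    tp = [p[1] for p in result.path]
    ax.plot(tp, qp, lw=1.2)
    ax.set_xlabel("template sample")
    ax.set_ylabel("query sample")
    fig.tight_layout()
    pathplot = out_prefix.with_name(out_prefix.name + f"_warping_path_{axis_name}.png")
    fig.savefig(pathplot, dpi=110)
    plt.close(fig)
    created.append(pathplot)
    return created
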