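"""Slope-constrained dynamic time warping for fall-signal comparison.

Aligns a *query* series (the real-world fall signal) onto a *template*
series (the re-enacted one) by dynamic programming over a slope-constrained
step pattern.  The pattern used throughout is the Sakoe–Chiba asymmetric
pattern with slope-constraint parameter P = 1 ("asymmetricP1"), which keeps
the local slope of the warping path within [1/2, 2] and advances the query
at every step, so the optimal cumulative distance normalizes naturally by
the query length N (the path weights always sum to N).

Open-begin / open-end alignment allows an unmatched template prefix /
suffix at zero cost (subsequence matching).  Open begin is realized, as in
the classic formulation, by a phantom zero-cost query row seeded to zero,
so a path may enter the template at any column — including through a
multi-cell slope rule.  Every query sample is always matched.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np

from .signals import TriaxialAccelerationSignal

#: A rule element: (query_offset, template_offset, weight), offsets measured
#: backward from the rule's end cell.  The first element of a rule is its
#: start cell and carries no weight.
RuleElement = Tuple[int, int, float]
Rule = Tuple[RuleElement, ...]


class AlignmentInfeasibleError(ValueError):
    """No admissible warping path exists under the slope constraints."""

    def __init__(self, query_length: int, template_length: int, message: str = ""):
        self.query_length = query_length
        self.template_length = template_length
        detail = message or (
            f"no admissible warping path for query length {query_length} and "
            f"template length {template_length} under the slope constraints"
        )
        super().__init__(detail)


@dataclass(frozen=True)
class StepPattern:
    """A set of local DP production rules plus a normalization kind.

    Each rule is an ordered chain of ``(query_offset, template_offset,
    weight)`` elements measured backward from the rule's end cell; the
    chain's start cell carries no weight.  Asymmetric-family invariants are
    enforced: every rule advances the query by at least one sample and its
    weights sum to its query advance.
    """

    pattern_id: str
    rules: Tuple[Rule, ...]
    normalization_kind: str = "query_length"

    def __post_init__(self) -> None:
        if self.normalization_kind != "query_length":
            raise ValueError(f"unsupported normalization kind {self.normalization_kind!r}")
        for rule in self.rules:
            dq0, dt0, _ = rule[0]
            if dq0 < 1:
                raise ValueError("every rule must advance the query by >= 1")
            if rule[-1][:2] != (0, 0):
                raise ValueError("a rule chain must end at the end cell (0, 0)")
            weights = [w for (_, _, w) in rule[1:]]
            if any(w < 0 for w in weights):
                raise ValueError("rule weights must be non-negative")
            if abs(sum(weights) - dq0) > 1e-12:
                raise ValueError(
                    f"rule weights must sum to the query advance {dq0}, got {sum(weights)}"
                )

    def query_advances(self) -> tuple[int, ...]:
        return tuple(rule[0][0] for rule in self.rules)

    def weight_sums(self) -> tuple[float, ...]:
        return tuple(sum(w for (_, _, w) in rule[1:]) for rule in self.rules)


def asymmetric_p1() -> StepPattern:
    """The Sakoe–Chiba asymmetric step pattern with slope constraint P = 1.

    Three rules end at cell (i, j):

    a. start (i-1, j-2), chain through (i, j-1) weight 0.5, end (i, j)
       weight 0.5  — local slope 1/2;
    b. start (i-1, j-1), end (i, j) weight 1  — diagonal;
    c. start (i-2, j-1), chain through (i-1, j) weight 1, end (i, j)
       weight 1  — local slope 2.

    The admissible local slope therefore lies in [1/2, 2], and the optimal
    cumulative distance divides by the query length.
    """
    rule_a: Rule = ((1, 2, 0.0), (0, 1, 0.5), (0, 0, 0.5))
    rule_b: Rule = ((1, 1, 0.0), (0, 0, 1.0))
    rule_c: Rule = ((2, 1, 0.0), (1, 0, 1.0), (0, 0, 1.0))
    return StepPattern("asymmetricP1", (rule_a, rule_b, rule_c))


def asymmetric() -> StepPattern:
    """The unconstrained asymmetric pattern (slope in [0, inf)).

    Provided for testing and comparison; the fall-signal workflow uses
    :func:`asymmetric_p1`.
    """
    return StepPattern(
        "asymmetric",
        (
            ((1, 0, 0.0), (0, 0, 1.0)),
            ((1, 1, 0.0), (0, 0, 1.0)),
            ((1, 2, 0.0), (0, 0, 1.0)),
        ),
    )


@dataclass
class AlignmentResult:
    """Outcome of one DTW alignment of a query onto a template."""

    cumulative_distance: float
    normalized_distance: float
    path: list[tuple[int, int]]
    template_match_start: int
    template_match_end: int
    step_pattern_id: str
    open_begin: bool
    open_end: bool
    query_length: int

    def to_json_dict(self) -> dict:
        return {
            "cumulative_distance": self.cumulative_distance,
            "normalized_distance": self.normalized_distance,
            "template_match_start": self.template_match_start,
            "template_match_end": self.template_match_end,
            "step_pattern_id": self.step_pattern_id,
            "open_begin": self.open_begin,
            "open_end": self.open_end,
            "query_length": self.query_length,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")

    def write_path_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["query_index", "template_index"])
            writer.writerows(self.path)


def normalized_distance(cumulative: float, query_length: int) -> float:
    """Cumulative weighted distance divided by the number of query samples."""
    if query_length <= 0:
        raise ValueError(f"query_length must be positive, got {query_length}")
    if cumulative < 0:
        raise ValueError(f"cumulative distance must be non-negative, got {cumulative}")
    return cumulative / query_length


def _local_cost_matrix(query: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pointwise Euclidean local cost; 1-D series use |q_i - t_j|."""
    if query.ndim == 1:
        return np.abs(query[:, None] - template[None, :])
    diff = query[:, None, :] - template[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def _shifted(row: np.ndarray, offset: int) -> np.ndarray:
    """Row shifted right by ``offset`` columns, inf-filled (inadmissible)."""
    if offset == 0:
        return row
    out = np.full_like(row, np.inf)
    out[offset:] = row[:-offset]
    return out


def dtw_align(
    query: Sequence[float],
    template: Sequence[float],
    pattern: StepPattern | None = None,
    open_begin: bool = False,
    open_end: bool = False,
) -> AlignmentResult:
    """Align ``query`` onto ``template`` with a slope-constrained step pattern.

    Parameters
    ----------
    query, template
        1-D series (or (n, k) arrays for multivariate alignment with a k-D
        Euclidean local distance; the fall workflow is univariate per axis).
        Both must have length >= 2.
    pattern
        Step pattern; defaults to :func:`asymmetric_p1`.
    open_begin, open_end
        Allow an unmatched template prefix / suffix at zero cost.

    Returns
    -------
    AlignmentResult
        Cumulative and query-normalized distance, the full warping path
        (including intermediate chain cells of multi-cell rules), and the
        matched template range.

    Raises
    ------
    AlignmentInfeasibleError
        When the slope constraints leave no admissible path (for example a
        closed-end alignment with template more than twice — or less than
        half — the query's span).

    Notes
    -----
    Ties in the DP minimization are broken deterministically: rules with a
    smaller total (query + template) advance are preferred, then earlier
    rules in the pattern's listed order.  For asymmetricP1 this prefers the
    diagonal rule, then the slope-1/2 rule, then the slope-2 rule.  Open-end
    ties prefer the earliest template column.
    """
    if pattern is None:
        pattern = asymmetric_p1()
    q = np.asarray(query, dtype=float)
    t = np.asarray(template, dtype=float)
    n, m = q.shape[0], t.shape[0]
    if n < 2 or m < 2:
        raise ValueError(f"both series need length >= 2, got query {n}, template {m}")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(t))):
        raise ValueError("series values must be finite")

    local = _local_cost_matrix(q, t)
    if open_begin:
        # phantom zero-cost query row: a path may start at any template column
        local = np.vstack([np.zeros((1, m)), local])
    n_rows = local.shape[0]

    g = np.full((n_rows, m), np.inf)
    choice = np.full((n_rows, m), -1, dtype=np.int8)
    if open_begin:
        g[0, :] = 0.0
    else:
        g[0, 0] = local[0, 0]

    rules = pattern.rules
    # deterministic tie-break: smallest total advance first, then listed order
    preference = sorted(
        range(len(rules)), key=lambda r: (rules[r][0][0] + rules[r][0][1], r)
    )
    candidates = np.empty((len(rules), m))
    for i in range(1, n_rows):
        candidates.fill(np.inf)
        for slot, r in enumerate(preference):
            rule = rules[r]
            dq0, dt0, _ = rule[0]
            if i - dq0 < 0:
                continue
            acc = _shifted(g[i - dq0], dt0).copy()
            for dq, dt, w in rule[1:]:
                if w:
                    acc += w * _shifted(local[i - dq], dt)
            candidates[slot] = acc
        best_slot = np.argmin(candidates, axis=0)  # first minimum wins
        g[i] = candidates[best_slot, np.arange(m)]
        reachable = np.isfinite(g[i])
        choice[i, reachable] = np.asarray(preference, dtype=np.int8)[best_slot[reachable]]
        if open_begin and i == 1:
            # direct starts: the path may begin at any cell (0, j) at cost
            # d(0, j) (free template prefix), besides the phantom-row
            # entries through multi-cell rules; direct start wins ties
            direct = local[1] <= g[1]
            g[1] = np.where(direct, local[1], g[1])
            choice[1, direct] = -2

    last = n_rows - 1
    if open_end:
        j_end = int(np.argmin(g[last]))
    else:
        j_end = m - 1
    cumulative = float(g[last, j_end])
    if not np.isfinite(cumulative):
        raise AlignmentInfeasibleError(n, m)

    # backtrack, collecting every chain cell of every applied rule
    cells_rev: list[tuple[int, int]] = []
    i, j = last, j_end
    while True:
        if i == 0:
            if not open_begin:
                cells_rev.append((0, 0))
            break
        if int(choice[i, j]) == -2:  # direct start of an open-begin path
            cells_rev.append((i, j))
            break
        rule = rules[int(choice[i, j])]
        for dq, dt, _ in reversed(rule[1:]):
            cells_rev.append((i - dq, j - dt))
        dq0, dt0, _ = rule[0]
        i, j = i - dq0, j - dt0
    path = cells_rev[::-1]
    if open_begin:
        path = [(qi - 1, tj) for (qi, tj) in path]

    return AlignmentResult(
        cumulative_distance=cumulative,
        normalized_distance=normalized_distance(cumulative, n),
        path=path,
        template_match_start=path[0][1],
        template_match_end=path[-1][1],
        step_pattern_id=pattern.pattern_id,
        open_begin=open_begin,
        open_end=open_end,
        query_length=n,
    )


def align_axis(
    query_signal: TriaxialAccelerationSignal,
    template_signal: TriaxialAccelerationSignal,
    axis: str,
    open_begin: bool = True,
    open_end: bool = True,
) -> AlignmentResult:
    """Align one axis of the query signal onto the same axis of the template.

    Both signals must share a sampling rate (resample first otherwise); the
    alignment uses :func:`asymmetric_p1`.
    """
    if query_signal.sampling_rate_hz != template_signal.sampling_rate_hz:
        raise ValueError(
            f"sampling rates differ ({query_signal.sampling_rate_hz} vs "
            f"{template_signal.sampling_rate_hz} Hz); resample first"
        )
    return dtw_align(
        query_signal.axis(axis),
        template_signal.axis(axis),
        asymmetric_p1(),
        open_begin=open_begin,
        open_end=open_end,
    )


def warp_template(template: Sequence[float], result: AlignmentResult) -> np.ndarray:
    """Stretch the template onto the query's time axis through the path.

    For each query index the template sample at the largest template index
    paired with it is taken; template samples matched to several query
    indices are thereby repeated.  The output always has the query's length.
    """
    t = np.asarray(template, dtype=float)
    out_index = np.full(result.query_length, -1, dtype=int)
    for qi, tj in result.path:
        if tj >= t.shape[0] or qi >= result.query_length:
            raise ValueError("alignment path is inconsistent with the template length")
        out_index[qi] = max(out_index[qi], tj)
    if np.any(out_index < 0):
        raise ValueError("alignment path does not cover every query index")
    return t[out_index]
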