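"""Independent oracles for the DTW core.

Two routes, both deliberately independent of the package's vectorized DP:

* :func:`enumerate_dtw_min` — exhaustive depth-first enumeration of every
  admissible rule sequence (feasible only for short series), returning the
  minimum weighted path cost.
* :func:`reference_dtw` — a per-cell memo-table implementation driven by
  the classic rule-row table of the Sakoe–Chiba asymmetric P=1 pattern
  (pattern id, query delta, template delta, weight), written with plain
  Python loops in the style of the original published recursion.

Open begin is realized in both by a phantom zero-cost query row that lets a
path start at any template column; open end takes the minimum over the last
query row.
"""

from __future__ import annotations

import math

# forward rules: (start advance (dq, dt), weighted cells as offsets back
# from the rule's end cell)
_ENUM_RULES = (
    ((1, 2), (((0, 1), 0.5), ((0, 0), 0.5))),
    ((1, 1), (((0, 0), 1.0),)),
    ((2, 1), (((1, 0), 1.0), ((0, 0), 1.0))),
)


def enumerate_dtw_min(query, template, open_begin=False, open_end=False):
    """Minimum cumulative cost over all admissible paths, or ``math.inf``.

    Exhaustive depth-first search; intended for series of length <= 8.
    """
    q = [float(v) for v in query]
    t = [float(v) for v in template]
    n, m = len(q), len(t)
    local = [[abs(qi - tj) for tj in t] for qi in q]
    best = math.inf

    stack: list[tuple[int, int, float]] = []
    if open_begin:
        # phantom-row entries (through any rule) and direct starts at (0, j)
        stack.extend((-1, j, 0.0) for j in range(m))
        stack.extend((0, j, local[0][j]) for j in range(m))
    else:
        stack.append((0, 0, local[0][0]))

    while stack:
        i, j, cost = stack.pop()
        if i == n - 1:
            if open_end or j == m - 1:
                best = min(best, cost)
            continue
        for (dq, dt), chain in _ENUM_RULES:
            ni, nj = i + dq, j + dt
            if ni > n - 1 or nj > m - 1:
                continue
            step = cost
            for (bq, bt), w in chain:
                step += w * local[ni - bq][nj - bt]
            stack.append((ni, nj, step))
    return best


# rule-row table: (pattern id, query delta, template delta, weight);
# weight -1 marks the start of a rule (no cost contribution)
_P1_TABLE = (
    (1, 1, 2, -1.0),
    (1, 0, 1, 0.5),
    (1, 0, 0, 0.5),
    (2, 1, 1, -1.0),
    (2, 0, 0, 1.0),
    (3, 2, 1, -1.0),
    (3, 1, 0, 1.0),
    (3, 0, 0, 1.0),
)


def reference_dtw(query, template, open_begin=False, open_end=False):
    """(cumulative, normalized) distances from a table-driven per-cell DP.

    Raises ``ValueError`` when no admissible path exists.
    """
    q = [float(v) for v in query]
    t = [float(v) for v in template]
    n, m = len(q), len(t)
    local = [[abs(qi - tj) for tj in t] for qi in q]
    if open_begin:
        local = [[0.0] * m] + local
    rows = len(local)

    # split the flat table into per-pattern element lists (start first)
    patterns: dict[int, list[tuple[int, int, float]]] = {}
    for pid, dq, dt, w in _P1_TABLE:
        patterns.setdefault(pid, []).append((dq, dt, w))

    g = [[math.inf] * m for _ in range(rows)]
    if open_begin:
        g[0] = [0.0] * m
    else:
        g[0][0] = local[0][0]
    for i in range(1, rows):
        for j in range(m):
            best = math.inf
            for elems in patterns.values():
                dq0, dt0, _ = elems[0]
                si, sj = i - dq0, j - dt0
                if si < 0 or sj < 0:
                    continue
                cost = g[si][sj]
                if cost == math.inf:
                    continue
                for dq, dt, w in elems[1:]:
                    cost += w * local[i - dq][j - dt]
                if cost < best:
                    best = cost
            if open_begin and i == 1 and local[i][j] < best:
                best = local[i][j]  # direct start at (0, j)
            g[i][j] = best

    final = min(g[rows - 1]) if open_end else g[rows - 1][m - 1]
    if final == math.inf:
        raise ValueError(f"no admissible path for lengths {n}, {m}")
    return final, final / n
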