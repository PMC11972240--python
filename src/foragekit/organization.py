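"""Spatial-organization indicators of a target-collection path.

Four indicators, each computed over the ordered screen coordinates of the
targets collected so far (for moving displays, the coordinates recorded at
the instant each target was captured):

* **best-r** — the larger absolute Pearson correlation between collection
  order (1, 2, …, n) and either screen coordinate; high for reading-like
  left–right or top–down scanning.
* **mean ITD** — arithmetic mean of the Euclidean distances between
  consecutively collected targets, in pixels.
* **PAO** — percentage above the optimal path:
  ``(actual / optimal − 1) × 100``, where *optimal* is the length of the
  shortest open Hamiltonian path through the same collection locations
  (a traveling-salesman-style lower bound).
* **intersection rate** — crossings between non-consecutive path segments,
  divided by the number of segments.

Lower mean ITD, PAO and intersection rate and higher best-r all indicate
a more organized search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .io import Trial

#: Largest n solved exactly (Held–Karp subset DP) when method="auto".
EXACT_MAX_N = 12


@dataclass(frozen=True)
class IndicatorSet:
    """The four indicators for one trial-so-far prefix of n picks."""

    n: int
    best_r: float
    mean_itd: float
    pao: float
    intersection_rate: float
    degenerate: bool = False  # any indicator hit a degenerate geometry


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, with zero-variance inputs contributing 0 by convention."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def best_r(coords) -> float:
    """Larger absolute correlation between collection order and x or y.

    A coordinate with zero variance contributes 0 to the maximum; if both
    coordinates are constant the result is 0 (degenerate path).
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 3:
        raise ValueError("best_r requires at least 3 picks")
    order = np.arange(1, len(pts) + 1, dtype=float)
    return max(abs(_pearson(order, pts[:, 0])), abs(_pearson(order, pts[:, 1])))


def mean_itd(coords) -> float:
    """Mean Euclidean distance between consecutively collected targets (px)."""
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 2:
        raise ValueError("mean_itd requires at least 2 picks")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).mean())


def path_length(coords) -> float:
    """Total length of the path visiting the points in the given order."""
    pts = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _held_karp_open(dist: np.ndarray, anchor_first: bool = False) -> float:
    """Exact shortest open Hamiltonian path by subset dynamic programming.

    ``dp[S][j]`` is the shortest path visiting exactly the points in bitmask
    ``S`` and ending at ``j``.  Endpoints are free unless ``anchor_first``,
    in which case every path starts at point 0.
    """
    n = len(dist)
    full = 1 << n
    INF = math.inf
    dp = np.full((full, n), INF)
    if anchor_first:
        dp[1, 0] = 0.0
    else:
        for j in range(n):
            dp[1 << j, j] = 0.0
    for S in range(1, full):
        row = dp[S]
        ends = np.nonzero(row < INF)[0]
        if len(ends) == 0:
            continue
        rest = [k for k in range(n) if not S & (1 << k)]
        for k in rest:
            cand = row[ends] + dist[ends, k]
            best = cand.min()
            T = S | (1 << k)
            if best < dp[T, k]:
                dp[T, k] = best
    return float(dp[full - 1].min())


def _two_opt(order: list[int], dist: np.ndarray, anchor_first: bool) -> float:
    # 2-opt: reverse order[i:j+1]; for an open path only the two boundary
    # edges change (a reversal touching an end drops one of them).
    improved = True
    while improved:
        improved = False
        for i in range(0 if not anchor_first else 1, len(order) - 1):
            for j in range(i + 1, len(order)):
                before = 0.0
                after = 0.0
                if i > 0:
                    before += dist[order[i - 1], order[i]]
                    after += dist[order[i - 1], order[j]]
                if j < len(order) - 1:
                    before += dist[order[j], order[j + 1]]
                    after += dist[order[i], order[j + 1]]
                if after < before - 1e-12:
                    order[i : j + 1] = reversed(order[i : j + 1])
                    improved = True
    return float(sum(dist[a, b] for a, b in zip(order, order[1:])))


def _path_len(order: list[int], dist: np.ndarray) -> float:
    idx = np.asarray(order)
    return float(dist[idx[:-1], idx[1:]].sum())


def _or_opt(order: list[int], dist: np.ndarray, anchor_first: bool) -> bool:
    """Relocate segments of 1–3 nodes (optionally reversed); returns
    whether the path improved."""
    n = len(order)
    best = _path_len(order, dist)
    improved = False
    changed = True
    while changed:
        changed = False
        for L in (1, 2, 3):
            for i in range(1 if anchor_first else 0, n - L + 1):
                seg = order[i : i + L]
                rest = order[:i] + order[i + L :]
                lo = 1 if anchor_first else 0
                for k in range(lo, len(rest) + 1):
                    if k == i:
                        continue
                    for piece in (seg, seg[::-1]):
                        cand = rest[:k] + piece + rest[k:]
                        length = _path_len(cand, dist)
                        if length < best - 1e-12:
                            order[:] = cand
                            best = length
                            improved = changed = True
    return improved


def _nn_two_opt(dist: np.ndarray, anchor_first: bool = False) -> float:
    """Nearest neighbor from every start, each refined by alternating
    2-opt and segment-relocation passes (open path)."""
    n = len(dist)
    if anchor_first:
        starts = [0]
    elif n <= 15:
        starts = list(range(n))
    else:  # cap the multi-start sweep on large instances
        starts = np.linspace(0, n - 1, 8).astype(int).tolist()
    best_len = math.inf
    for s in starts:
        unvisited = set(range(n)) - {s}
        order = [s]
        while unvisited:
            last = order[-1]
            nxt = min(unvisited, key=lambda k: dist[last, k])
            order.append(nxt)
            unvisited.remove(nxt)
        length = _two_opt(order, dist, anchor_first)
        while _or_opt(order, dist, anchor_first):
            length = _two_opt(order, dist, anchor_first)
        best_len = min(best_len, _path_len(order, dist))
    return best_len


def optimal_path_length(
    points,
    method: str = "auto",
    exact_max_n: int = EXACT_MAX_N,
    anchor_first: bool = False,
) -> float:
    """Length of the shortest open Hamiltonian path through ``points``.

    Endpoints are unconstrained by default (``anchor_first=True`` forces
    the path to start at the first point, matching the alternative reading
    where the optimal path begins where collection began).

    ``method="exact"`` runs Held–Karp subset DP (feasible to n ≈ 15);
    ``"heuristic"`` runs best-of-all-starts nearest neighbor plus 2-opt,
    which never undercuts the exact optimum; ``"auto"`` switches at
    ``exact_max_n``.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("optimal_path_length requires at least 2 points")
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if method == "auto":
        method = "exact" if n <= exact_max_n else "heuristic"
    if method == "exact":
        if n > max(exact_max_n, 15):
            raise ValueError(
                f"exact solver capped at n={max(exact_max_n, 15)}, got {n}"
            )
        return _held_karp_open(dist, anchor_first)
    if method == "heuristic":
        return _nn_two_opt(dist, anchor_first)
    raise ValueError(f"unknown method {method!r}")


def pao(coords, method: str = "auto", anchor_first: bool = False) -> float:
    """Percentage above the optimal path:
    ``(actual path length / optimal path length − 1) × 100``.

    Returns ``nan`` (degenerate) when all points coincide, i.e. the
    optimal length is 0.
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 3:
        raise ValueError("pao requires at least 3 picks")
    optimal = optimal_path_length(pts, method=method, anchor_first=anchor_first)
    if optimal == 0.0:
        return float("nan")
    actual = path_length(pts)
    return (actual / optimal - 1.0) * 100.0


def intersection_rate(coords, per_target: bool = False) -> float:
    """Intersections between non-consecutive scan-path segments, per segment.

    Segment i joins pick i to pick i+1.  Every pair (i, j) with j ≥ i+2
    that shares at least one point — a proper crossing, an endpoint touch,
    or a collinear overlap — counts as one intersection.  The count is
    divided by the number of segments (n − 1), or by the number of targets
    n when ``per_target`` is set.
    """
    pts = np.asarray(coords, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("intersection_rate requires at least 3 picks")
    segs = [LineString([pts[i], pts[i + 1]]) for i in range(n - 1)]
    count = sum(
        1
        for i in range(len(segs))
        for j in range(i + 2, len(segs))
        if segs[i].intersects(segs[j])
    )
    return count / (n if per_target else n - 1)


def indicators(
    coords,
    method: str = "auto",
    anchor_first: bool = False,
    per_target: bool = False,
) -> IndicatorSet:
    """All four indicators on one collection path of n ≥ 3 picks."""
    pts = np.asarray(coords, dtype=float)
    br = best_r(pts)
    itd = mean_itd(pts)
    p = pao(pts, method=method, anchor_first=anchor_first)
    ir = intersection_rate(pts, per_target=per_target)
    degenerate = math.isnan(p) or (np.ptp(pts[:, 0]) == 0 and np.ptp(pts[:, 1]) == 0)
    return IndicatorSet(
        n=len(pts),
        best_r=br,
        mean_itd=itd,
        pao=p,
        intersection_rate=ir,
        degenerate=degenerate,
    )


def indicator_series(
    trial: Trial,
    method: str = "auto",
    anchor_first: bool = False,
    per_target: bool = False,
) -> list[IndicatorSet]:
    """Trial-so-far indicator series: element n is computed on the first n
    collected targets only, for n = 3 … N.

    The optimal path is re-solved from scratch at every prefix, so each
    element is exactly the value an observer's record would have shown had
    the trial ended at that pick (prefix property).  Degenerate geometries
    are flagged on the element, never raised.
    """
    coords = np.asarray(trial.target_coords(), dtype=float)
    return [
        indicators(
            coords[:n], method=method, anchor_first=anchor_first, per_target=per_target
        )
        for n in range(3, len(coords) + 1)
    ]
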