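"""Independent brute-force oracles used by the test suite.

Deliberately naive: exhaustive vertex enumeration for the flux LP,
O(n^2) pairwise sweeps for interval operations, and a literal step-up
loop for Benjamini-Hochberg.  None of these share code with the package.
"""

from itertools import combinations, product

import numpy as np


def lp_vertex_maximum(S: np.ndarray, ub: np.ndarray, c: np.ndarray) -> float:
    """max c.v over {S v = 0, 0 <= v <= ub} by enumerating polytope vertices.

    Every vertex has at least n - rank(S) components at a bound; enumerate
    all choices of basic columns and bound assignments for the rest.
    Only feasible for small n (<= ~10).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    best = None
    for basic in combinations(range(n), r):
        nonbasic = [j for j in range(n) if j not in basic]
        SB = S[:, list(basic)]
        for bounds_choice in product(*[(0.0, ub[j]) for j in nonbasic]):
            v = np.zeros(n)
            for j, val in zip(nonbasic, bounds_choice):
                v[j] = val
            rhs = -S[:, nonbasic] @ np.array(bounds_choice) if nonbasic else np.zeros(S.shape[0])
            if r:
                xb, *_ = np.linalg.lstsq(SB, rhs, rcond=None)
                v[list(basic)] = xb
            if np.abs(S @ v).max() > 1e-8:
                continue
            if (v < -1e-9).any() or (v > ub + 1e-9).any():
                continue
            obj = float(c @ v)
            if best is None or obj > best:
                best = obj
    assert best is not None, "polytope has no vertex (v=0 should always qualify)"
    return best


def merge_intervals_naive(intervals):
    """Coalesce overlapping/bookended (chrom, start, end) triples, O(n^2)."""
    out = []
    for chrom in sorted({c for c, _, _ in intervals}):
        group = sorted((s, e) for c, s, e in intervals if c == chrom)
        merged = []
        for s, e in group:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out += [(chrom, s, e) for s, e in merged]
    return sorted(out)


def intersect_intervals_naive(a, b):
    """All pairwise overlapping portions of two (chrom, start, end) lists."""
    out = []
    for ca, sa, ea in a:
        for cb, sb, eb in b:
            if ca == cb and sa < eb and sb < ea:
                out.append((ca, max(sa, sb), min(ea, eb)))
    return sorted(out)


def bh_adjust_naive(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
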