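"""Small interval utilities on BED-style 0-based half-open coordinates.

These are deliberately minimal: any-overlap tests, covered-base fractions
against a merged interval union, and nearest-point distances, vectorized with
numpy. All functions operate within a single chromosome; callers group by
chromosome.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge_intervals", "any_overlap", "covered_fraction", "point_to_interval_distance"]


def merge_intervals(starts, ends):
    """Merge overlapping/adjacent half-open intervals; returns sorted (starts, ends)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def any_overlap(q_starts, q_ends, t_starts, t_ends):
    """Boolean per query interval: does it overlap any target interval?

    Half-open semantics: [a, b) and [c, d) overlap iff a < d and c < b.
    Targets need not be merged.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    ms, me = merge_intervals(t_starts, t_ends)
    if ms.size == 0:
        return np.zeros(q_starts.shape, dtype=bool)
    # candidate merged interval: last one starting before the query end
    idx = np.searchsorted(ms, q_ends, side="left") - 1
    hit = idx >= 0
    hit[hit] = me[idx[hit]] > q_starts[hit]
    return hit


def covered_fraction(q_starts, q_ends, t_starts, t_ends):
    """Fraction of bases of each query covered by the union of targets."""
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    ms, me = merge_intervals(t_starts, t_ends)
    out = np.zeros(len(q_starts), dtype=float)
    if ms.size == 0:
        return out
    # cumulative covered bases up to each merged-interval end
    cum = np.concatenate([[0], np.cumsum(me - ms)])

    def covered_upto(pos):
        # bases of the union strictly before position `pos`
        i = np.searchsorted(ms, pos, side="right")
        j = np.maximum(i - 1, 0)
        part = np.clip(np.minimum(pos, me[j]) - ms[j], 0, None)
        return np.where(i > 0, cum[j] + part, 0)

    width = (q_ends - q_starts).astype(float)
    cov = covered_upto(q_ends) - covered_upto(q_starts)
    np.divide(cov, width, out=out, where=width > 0)
    return np.clip(out, 0.0, 1.0)


def point_to_interval_distance(points, starts, ends):
    """Distance from each point to the nearest base of its own interval (elementwise).

    Zero when the point lies inside [start, end); otherwise gap to the closest
    included base (end-1 for the right edge).
    """
    points = np.asarray(points, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    below = np.maximum(starts - points, 0)
    above = np.maximum(points - (ends - 1), 0)
    return below + above
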