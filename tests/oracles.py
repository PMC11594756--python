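"""Independent brute-force reference implementations used only by the tests.

Each oracle recomputes a quantity from the raw definition with the simplest
possible code (explicit scans, nested loops, textbook formulas) and shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

from bisect import bisect_right

import numpy as np

TICKS_PER_MS = 100  # 0.01 ms grid, matching the package's stated resolution


def oracle_detect_bursts(rec, params):
    """Exhaustive window-scan network-burst detector.

    Tests every window anchored at each spike, merges overlapping/abutting
    qualifying windows, and reports per-burst span/counts/peak on the same
    integer grid the package states it uses.
    """
    events = sorted(
        (int(round(t * 1000 * TICKS_PER_MS)), str(e))
        for e, ts in rec.spikes.items()
        for t in ts
    )
    if not events:
        return []
    times = [t for t, _ in events]
    W = int(round(params.window_ms * TICKS_PER_MS))

    qualifying = []
    for i, (t, _) in enumerate(events):
        j = bisect_right(times, t + W)
        window = events[i:j]
        electrodes = {e for _, e in window}
        if len(window) >= params.min_spikes and len(electrodes) >= params.min_electrodes:
            qualifying.append((t, t + W))

    merged = []
    for lo, hi in qualifying:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))

    bursts = []
    for lo, hi in merged:
        covered = [(t, e) for (t, e) in events if lo <= t <= hi]
        span_times = [t for t, _ in covered]
        peak = max(
            sum(1 for u in span_times if a <= u <= a + W) for a in span_times
        )
        bursts.append(
            {
                "start_ticks": min(span_times),
                "end_ticks": max(span_times),
                "total_spikes": len(covered),
                "n_electrodes": len({e for _, e in covered}),
                "peak_rate": peak,
                "size_class": "large" if peak > params.large_threshold else "small",
            }
        )
    return bursts


def oracle_sync_counts(source_ticks, target_ticks, max_delay_ms=50):
    """Nested-loop delayed-synchrony counts over every spike pair and window."""
    counts = []
    for k in range(1, max_delay_ms + 1):
        horizon = k * TICKS_PER_MS
        c = 0
        for b in target_ticks:
            if any(0 < b - a <= horizon for a in source_ticks):
                c += 1
        counts.append(c)
    return np.array(counts)


def oracle_kruskal_h(groups):
    """Kruskal-Wallis H from the raw rank-sum formula with tie correction."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank, 1-based
        i = j
    h = 0.0
    start = 0
    for g in groups:
        sz = len(g)
        r = ranks[start : start + sz].sum()
        h += r * r / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / float(n**3 - n)
    return h / correction


def oracle_diameter(edges, nodes):
    """Longest finite shortest path via Floyd-Warshall on the undirected graph."""
    nodes = sorted(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, v in edges:
        i, j = index[u], index[v]
        dist[i][j] = dist[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    finite = [d for row in dist for d in row if d < inf]
    return max(finite) if finite else 0
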