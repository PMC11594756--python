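"""Network-burst detection, small/large classification and burst statistics.

A network burst is a population event in which at least ``min_spikes`` spikes
from at least ``min_electrodes`` distinct electrodes fall within a
``window_ms`` (default 50 ms) interval.  Detection slides a window anchored at
every spike; all qualifying windows are merged when they overlap or abut, and
each merged run becomes one burst whose span runs from the first to the last
spike it covers.  This construction is deterministic, independent of input
ordering, and checkable against an exhaustive window-scan oracle.

Bursts are classified by their *amplitude* — the peak spike count in any
window_ms-wide window inside the span: amplitude ``<= large_threshold``
(default 100 spikes per 50 ms) is a small burst, above it a large burst.

Per-recording statistics cover the five standard spontaneous-activity
parameters: burst rate, spikes per burst, burst duration, burst amplitude
(each split by size class) and the proportion of all recorded spikes that
fall inside burst spans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spikeio import RecordingBundle, SpikeTrainSet, TICKS_PER_SECOND, to_ticks

TICKS_PER_MS = TICKS_PER_SECOND // 1000

SMALL = "small"
LARGE = "large"


class ParameterError(ValueError):
    """Raised for invalid detection parameters."""


@dataclass(frozen=True)
class BurstDetectionParams:
    """Network-burst detection thresholds.

    window_ms
        Width of the detection window (ms).
    min_spikes
        Minimum spikes inside one window for it to qualify.
    min_electrodes
        Minimum distinct electrodes contributing to one qualifying window.
    large_threshold
        Small/large boundary on the peak spikes-per-window amplitude;
        a burst with amplitude exactly at the threshold is small.
    """

    window_ms: float = 50.0
    min_spikes: int = 4
    min_electrodes: int = 4
    large_threshold: int = 100

    def __post_init__(self) -> None:
        if not self.window_ms > 0:
            raise ParameterError("window_ms must be > 0")
        if self.min_spikes < 1 or self.min_electrodes < 1:
            raise ParameterError("min_spikes and min_electrodes must be >= 1")
        if self.large_threshold < self.min_spikes:
            raise ParameterError("large_threshold must be >= min_spikes")

    @property
    def window_ticks(self) -> int:
        return int(round(self.window_ms * TICKS_PER_MS))


@dataclass
class NetworkBurst:
    """One detected network burst."""

    start_s: float
    end_s: float
    total_spikes: int
    per_electrode_counts: dict[str, int]
    n_electrodes: int
    peak_rate: int  # amplitude: max spikes in any window_ms window in the span
    size_class: str = field(default=SMALL)

    @property
    def duration_ms(self) -> float:
        return (self.end_s - self.start_s) * 1000.0


def classify_burst(b: NetworkBurst, p: BurstDetectionParams) -> str:
    """Small if the peak spikes-per-window amplitude is <= large_threshold."""
    return LARGE if b.peak_rate > p.large_threshold else SMALL


def detect_network_bursts(
    s: SpikeTrainSet, p: BurstDetectionParams | None = None
) -> list[NetworkBurst]:
    """Detect network bursts in a recording.

    Returns disjoint bursts ordered by start time.  Every burst contains at
    least one window satisfying both the spike-count and distinct-electrode
    thresholds; the burst span is the maximal union of overlapping/abutting
    qualifying windows, clipped to the covered spikes.
    """
    if p is None:
        p = BurstDetectionParams()
    ticks, eidx = s.merged()
    n = ticks.size
    if n == 0:
        return []
    W = p.window_ticks

    # sliding window [t_i, t_i + W], two pointers, electrode multiset
    counts = np.zeros(len(s.electrode_ids), dtype=np.int64)
    distinct = 0
    j = 0  # exclusive right edge
    qual_start: list[int] = []
    for i in range(n):
        if j < i:
            j = i
            counts[:] = 0
            distinct = 0
        while j < n and ticks[j] <= ticks[i] + W:
            if counts[eidx[j]] == 0:
                distinct += 1
            counts[eidx[j]] += 1
            j += 1
        if j - i >= p.min_spikes and distinct >= p.min_electrodes:
            qual_start.append(i)
        counts[eidx[i]] -= 1
        if counts[eidx[i]] == 0:
            distinct -= 1

    if not qual_start:
        return []

    # merge overlapping/abutting qualifying windows [t_i, t_i + W]
    merged: list[list[int]] = []
    for i in qual_start:
        lo, hi = ticks[i], ticks[i] + W
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    bursts = []
    for lo, hi in merged:
        a = int(np.searchsorted(ticks, lo, side="left"))
        b = int(np.searchsorted(ticks, hi, side="right"))
        span_t = ticks[a:b]
        span_e = eidx[a:b]
        per = {}
        for e, c in zip(*np.unique(span_e, return_counts=True)):
            per[s.electrode_ids[e]] = int(c)
        peak = _peak_window_count(span_t, W)
        burst = NetworkBurst(
            start_s=span_t[0] / TICKS_PER_SECOND,
            end_s=span_t[-1] / TICKS_PER_SECOND,
            total_spikes=int(span_t.size),
            per_electrode_counts=per,
            n_electrodes=len(per),
            peak_rate=peak,
        )
        burst.size_class = classify_burst(burst, p)
        bursts.append(burst)
    return bursts


def _peak_window_count(span_ticks: np.ndarray, window_ticks: int) -> int:
    """Max number of span spikes inside any window anchored at a span spike."""
    right = np.searchsorted(span_ticks, span_ticks + window_ticks, side="right")
    return int((right - np.arange(span_ticks.size)).max())


# ---------------------------------------------------------------------------
# statistics


@dataclass
class BurstStatistics:
    """The five spontaneous-activity parameters, split by burst size class.

    Means over an empty class are NaN (missing), never zero.  With zero
    recorded spikes the rates are 0 and ``pct_spikes_in_bursts`` is NaN.
    """

    n_small_per_min: float
    n_large_per_min: float
    mean_spikes_small: float
    mean_spikes_large: float
    mean_duration_small_ms: float
    mean_duration_large_ms: float
    mean_amplitude_small: float
    mean_amplitude_large: float
    pct_spikes_in_bursts: float
    total_spikes: int = 0
    n_bursts: int = 0

    def as_dict(self) -> dict[str, float]:
        return dict(vars(self))


METRIC_COLUMNS = [
    "n_small_per_min",
    "n_large_per_min",
    "mean_spikes_small",
    "mean_spikes_large",
    "mean_duration_small_ms",
    "mean_duration_large_ms",
    "mean_amplitude_small",
    "mean_amplitude_large",
    "pct_spikes_in_bursts",
]


def spikes_in_burst_spans(s: SpikeTrainSet, bursts: list[NetworkBurst]) -> int:
    """Number of spikes falling inside any burst span (spans are disjoint)."""
    if not bursts:
        return 0
    ticks, _ = s.merged()
    total = 0
    for b in bursts:
        lo, hi = to_ticks(b.start_s), to_ticks(b.end_s)
        total += int(
            np.searchsorted(ticks, hi, side="right")
            - np.searchsorted(ticks, lo, side="left")
        )
    return total


def compute_burst_statistics(
    s: SpikeTrainSet, bursts: list[NetworkBurst]
) -> BurstStatistics:
    """Summarise detected bursts into per-recording activity parameters."""
    minutes = s.duration_s / 60.0
    small = [b for b in bursts if b.size_class == SMALL]
    large = [b for b in bursts if b.size_class == LARGE]
    total = s.n_spikes
    in_bursts = spikes_in_burst_spans(s, bursts)

    def _mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else math.nan

    return BurstStatistics(
        n_small_per_min=len(small) / minutes,
        n_large_per_min=len(large) / minutes,
        mean_spikes_small=_mean([b.total_spikes for b in small]),
        mean_spikes_large=_mean([b.total_spikes for b in large]),
        mean_duration_small_ms=_mean([b.duration_ms for b in small]),
        mean_duration_large_ms=_mean([b.duration_ms for b in large]),
        mean_amplitude_small=_mean([b.peak_rate for b in small]),
        mean_amplitude_large=_mean([b.peak_rate for b in large]),
        pct_spikes_in_bursts=(100.0 * in_bursts / total) if total else math.nan,
        total_spikes=total,
        n_bursts=len(bursts),
    )


def bursts_table(bursts: list[NetworkBurst]) -> pd.DataFrame:
    """Burst list as a tidy table (one row per burst)."""
    return pd.DataFrame(
        [
            {
                "start_s": b.start_s,
                "end_s": b.end_s,
                "duration_ms": b.duration_ms,
                "total_spikes": b.total_spikes,
                "n_electrodes": b.n_electrodes,
                "peak_rate": b.peak_rate,
                "size_class": b.size_class,
            }
            for b in bursts
        ],
        columns=[
            "start_s",
            "end_s",
            "duration_ms",
            "total_spikes",
            "n_electrodes",
            "peak_rate",
            "size_class",
        ],
    )


def longitudinal_summary(
    bundle: RecordingBundle,
    p: BurstDetectionParams | None = None,
    baseline_div: int = 14,
) -> pd.DataFrame:
    """Per-recording burst statistics across the group x DIV design.

    One row per recording, keyed by (group, div, recording_id), with the
    activity parameters as columns plus ``fold_<metric>`` columns holding the
    ratio of each value to its group's mean at ``baseline_div``.  Groups
    without a baseline DIV get NaN fold changes (and a logged warning).
    """
    import logging

    rows = []
    for group, div, rec in bundle.iter_design():
        bursts = detect_network_bursts(rec, p)
        stats = compute_burst_statistics(rec, bursts)
        row = {"group": group, "div": div, "recording_id": rec.meta["recording_id"]}
        row.update(stats.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for metric in METRIC_COLUMNS:
        df[f"fold_{metric}"] = np.nan
    for group, sub in df.groupby("group"):
        base = sub[sub["div"] == baseline_div]
        if base.empty:
            logging.getLogger(__name__).warning(
                "group %r has no DIV%d baseline; fold changes left missing",
                group,
                baseline_div,
            )
            continue
        for metric in METRIC_COLUMNS:
            base_mean = base[metric].mean()
            if not np.isfinite(base_mean) or base_mean == 0:
                continue
            df.loc[sub.index, f"fold_{metric}"] = sub[metric] / base_mean
    return df


def minute_by_minute(
    s: SpikeTrainSet, p: BurstDetectionParams | None = None
) -> pd.DataFrame:
    """Burst statistics per one-minute segment of a recording."""
    from .spikeio import split_minutes

    rows = []
    for seg in split_minutes(s):
        bursts = detect_network_bursts(seg, p)
        stats = compute_burst_statistics(seg, bursts)
        row = {"minute": seg.meta["segment_index"]}
        row.update(stats.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
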