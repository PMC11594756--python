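"""Delay-synchrony functional connectivity graphs for MEA recordings.

For an ordered electrode pair (m, n) — signal assumed to pass from m to n —
fifty cumulative delay windows of 1..50 ms are examined: a spike on n is
*synchronous with delay* at window length k if at least one spike on m
precedes it by some d in (0, k] ms.  ``counts[k]`` is the number of such
target spikes (each counted once per k, so counts are nondecreasing in k) and
``ratios[k] = counts[k] / (total spikes on n)``.  Pairs are ranked by the
ratio at the longest window, the top 5% of positive-score ordered pairs
become the edges of a directed graph, and hub/diameter metrics summarise its
architecture.

Profiles are computed by default on spikes inside large network-burst spans,
because large bursts are the events that expose network structure to
cross-correlation; this restriction is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .bursts import LARGE, NetworkBurst
from .spikeio import SpikeTrainSet, TICKS_PER_SECOND, to_ticks

TICKS_PER_MS = TICKS_PER_SECOND // 1000

#: which spikes enter the pair profiles
RESTRICT_LARGE = "large_bursts"
RESTRICT_ALL_BURSTS = "all_bursts"
RESTRICT_NONE = "all_spikes"


@dataclass
class PairSyncProfile:
    """Delayed-synchrony profile of one ordered electrode pair m -> n."""

    source: str
    target: str
    counts: np.ndarray  # int, counts[k-1] for k = 1..max_delay_ms
    n_target_spikes: int
    score: float = field(init=False)
    best_delay_ms: int = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        total = self.counts[-1]
        if self.n_target_spikes == 0 or total == 0:
            self.score = 0.0
            self.best_delay_ms = int(self.counts.size)
        else:
            self.score = float(total / self.n_target_spikes)
            # half-rise delay: smallest k whose count reaches half the final count
            half = 0.5 * total
            self.best_delay_ms = int(np.argmax(self.counts >= half) + 1)

    @property
    def ratios(self) -> np.ndarray:
        if self.n_target_spikes == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_target_spikes


def restrict_to_bursts(
    s: SpikeTrainSet,
    bursts: Sequence[NetworkBurst],
    restrict: str = RESTRICT_LARGE,
) -> dict[str, np.ndarray]:
    """Per-electrode spike ticks, optionally restricted to burst spans."""
    spans: list[tuple[int, int]] | None
    if restrict == RESTRICT_NONE:
        spans = None
    elif restrict == RESTRICT_ALL_BURSTS:
        spans = [(to_ticks(b.start_s), to_ticks(b.end_s)) for b in bursts]
    elif restrict == RESTRICT_LARGE:
        spans = [
            (to_ticks(b.start_s), to_ticks(b.end_s))
            for b in bursts
            if b.size_class == LARGE
        ]
    else:
        raise ValueError(f"unknown spike restriction {restrict!r}")
    out = {}
    for eid in s.electrode_ids:
        t = to_ticks(s.spikes[eid])
        if spans is None:
            out[eid] = t
        elif not spans:
            out[eid] = t[:0]
        else:
            keep = np.zeros(t.size, dtype=bool)
            for lo, hi in spans:
                a = np.searchsorted(t, lo, side="left")
                b = np.searchsorted(t, hi, side="right")
                keep[a:b] = True
            out[eid] = t[keep]
    return out


def _sync_counts(
    source_ticks: np.ndarray, target_ticks: np.ndarray, max_delay_ms: int
) -> np.ndarray:
    """counts[k-1] = #{target spikes with >=1 source spike preceding by (0, k] ms}.

    The minimal strictly-positive gap to a preceding source spike decides the
    smallest window at which a target spike is counted; the counts are the
    cumulative histogram of those gaps over the 1 ms delay grid.
    """
    counts = np.zeros(max_delay_ms, dtype=np.int64)
    if source_ticks.size == 0 or target_ticks.size == 0:
        return counts
    # last source spike strictly before each target spike gives the minimal
    # positive gap (simultaneous spikes are not "preceding": delay must be > 0)
    idx = np.searchsorted(source_ticks, target_ticks, side="left") - 1
    valid = idx >= 0
    gaps = target_ticks[valid] - source_ticks[idx[valid]]
    # gap g ticks is within (0, k] ms iff g <= k * TICKS_PER_MS
    kmin = np.ceil(gaps / TICKS_PER_MS).astype(np.int64)
    kmin = kmin[kmin <= max_delay_ms]
    if kmin.size:
        np.add.at(counts, kmin - 1, 1)
        counts = np.cumsum(counts)
    return counts


def pair_sync_profile(
    s: SpikeTrainSet,
    bursts: Sequence[NetworkBurst],
    m: str,
    n: str,
    max_delay_ms: int = 50,
    restrict: str = RESTRICT_LARGE,
) -> PairSyncProfile:
    """Profile one ordered pair; see module docstring for the definition."""
    if m == n:
        raise ValueError("source and target electrodes must differ")
    ticks = restrict_to_bursts(s, bursts, restrict)
    return PairSyncProfile(
        source=str(m),
        target=str(n),
        counts=_sync_counts(ticks[str(m)], ticks[str(n)], max_delay_ms),
        n_target_spikes=int(ticks[str(n)].size),
    )


def all_pair_profiles(
    s: SpikeTrainSet,
    bursts: Sequence[NetworkBurst],
    max_delay_ms: int = 50,
    restrict: str = RESTRICT_LARGE,
) -> list[PairSyncProfile]:
    """Profiles for every ordered pair of electrodes with in-scope spikes."""
    ticks = restrict_to_bursts(s, bursts, restrict)
    active = [e for e in s.electrode_ids if ticks[e].size > 0]
    profiles = []
    for m in active:
        for n in active:
            if m == n:
                continue
            profiles.append(
                PairSyncProfile(
                    source=m,
                    target=n,
                    counts=_sync_counts(ticks[m], ticks[n], max_delay_ms),
                    n_target_spikes=int(ticks[n].size),
                )
            )
    return profiles


def rank_pairs(profiles: Iterable[PairSyncProfile]) -> list[PairSyncProfile]:
    """Descending by score; ties broken by smaller best delay, then (m, n)."""
    return sorted(
        profiles,
        key=lambda p: (-p.score, p.best_delay_ms, p.source, p.target),
    )


@dataclass
class ConnectivityGraph:
    """Directed functional-connectivity graph of the top-ranked pairs."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def degrees(self) -> dict[str, int]:
        """In+out connection count per node."""
        return {v: self.graph.in_degree(v) + self.graph.out_degree(v) for v in self.graph}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "delay_ms": d["delay_ms"],
                "score": d["score"],
            }
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "delay_ms", "score"])


def build_connectivity_graph(
    ranked: Sequence[PairSyncProfile], top_fraction: float = 0.05
) -> ConnectivityGraph:
    """Keep the top ``ceil(top_fraction * P)`` of the P positive-score pairs.

    Zero-score pairs are never selected; with no positive pair the graph is
    empty.  The ceiling guarantees at least one edge whenever any delayed
    synchrony exists.
    """
    positive = [p for p in ranked if p.score > 0]
    g = nx.DiGraph()
    if positive:
        n_sel = math.ceil(top_fraction * len(positive))
        for p in positive[:n_sel]:
            g.add_edge(p.source, p.target, delay_ms=p.best_delay_ms, score=p.score)
    return ConnectivityGraph(graph=g)


def hub_metrics(
    g: ConnectivityGraph, hub_quantile: float = 0.90
) -> tuple[list[str], float, int]:
    """Hub nodes, hub coefficient and graph diameter.

    Hubs are nodes whose connection count reaches the ``hub_quantile``
    quantile of the (nonzero) node degrees, with a floor of two connections.
    The hub coefficient is the mean connection count over hubs (NaN when
    there are none).  The diameter is the longest finite shortest-path length
    (in edges) on the underlying undirected graph, 0 for fewer than 2 nodes.
    """
    degs = g.degrees
    if not degs:
        return [], math.nan, 0
    values = np.array(sorted(degs.values()))
    threshold = max(float(np.quantile(values, hub_quantile)), 2.0)
    hubs = sorted(v for v, d in degs.items() if d >= threshold)
    hub_coefficient = (
        float(np.mean([degs[v] for v in hubs])) if hubs else math.nan
    )
    und = g.graph.to_undirected()
    diameter = 0
    for comp in nx.connected_components(und):
        if len(comp) < 2:
            continue
        ecc = nx.eccentricity(und.subgraph(comp))
        diameter = max(diameter, max(ecc.values()))
    return hubs, hub_coefficient, diameter


def node_table(g: ConnectivityGraph, hub_quantile: float = 0.90) -> pd.DataFrame:
    hubs, _, _ = hub_metrics(g, hub_quantile)
    hubset = set(hubs)
    degs = g.degrees
    return pd.DataFrame(
        [
            {"electrode": v, "degree": degs[v], "is_hub": v in hubset}
            for v in sorted(degs)
        ],
        columns=["electrode", "degree", "is_hub"],
    )


def write_graphml(g: ConnectivityGraph, path) -> None:
    nx.write_graphml(g.graph, path)
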