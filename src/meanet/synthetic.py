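"""Synthetic MEA recordings with known ground truth.

The generator emulates what the analysis pipeline must measure — tonic
background spiking, hub-initiated propagating network bursts, directed
delayed-synchrony structure, and graded suppression of all three under an
amyloidosis-like condition factor — with the simplest mechanism that
produces those observables.  It is not a biophysical neuron model.

Mechanism, per recording:

* Network-burst onsets follow a homogeneous Poisson process with rate
  ``burst_rate_per_min * delta``.
* At each burst, every hub electrode activates at the onset plus an
  independent uniform offset (``hub_offset_spread_ms``), and activation
  propagates along the planted directed edges: an edge m -> n fires its
  target with probability ``transmission_prob * delta`` at the *source's*
  activation time plus ``delay_ms`` plus Gaussian jitter.  Delays therefore
  compose along paths, so consecutive edges create time-locked lags at the
  cumulative delay — exactly the structure the delay-synchrony statistic is
  built to detect.
* Every activated electrode emits a volley of ``Poisson(spikes_per_electrode
  * delta * vigor)`` spikes spread uniformly over ``burst_envelope_ms``,
  where ``vigor`` is a per-burst lognormal factor capturing the large
  burst-to-burst variability of real cultures.
* Background spikes are an independent homogeneous Poisson train per
  electrode at ``background_rate_hz`` (not scaled by delta: the condition
  suppresses coordinated bursting, while isolated spikes persist).

The condition factor ``delta`` multiplies the burst rate, the per-electrode
in-burst spike count and the transmission probability jointly: ``delta = 1``
is an intact culture, ``delta < 1`` graded amyloid suppression, and because
the large-burst classification thresholds the peak spike rate, moderate
``delta`` already collapses large-burst counts while small bursts persist —
mirroring the phenotype of amyloid-exposed cultures.

Identical ``(config, seed)`` reproduce byte-identical spike tables.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .spikeio import (
    MEA60_LAYOUT,
    RecordingBundle,
    SpikeTrainSet,
    TICKS_PER_SECOND,
    to_ticks,
)


class ParameterError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class PlantedEdge:
    """A directed functional connection m -> n with a fixed propagation delay."""

    source: str
    target: str
    delay_ms: float
    transmission_prob: float = 0.85
    jitter_ms: float = 0.5

    def __post_init__(self) -> None:
        if not (1.0 <= self.delay_ms <= 50.0):
            raise ParameterError(f"delay_ms must be in [1, 50], got {self.delay_ms}")
        if not (0.0 <= self.transmission_prob <= 1.0):
            raise ParameterError("transmission_prob must be in [0, 1]")
        if self.jitter_ms < 0:
            raise ParameterError("jitter_ms must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults emulate an intact 60-electrode culture."""

    n_electrodes: int = 60
    duration_s: float = 600.0
    background_rate_hz: float = 0.1
    burst_rate_per_min: float = 8.0
    hub_electrodes: tuple[str, ...] = ()
    planted_edges: tuple[PlantedEdge, ...] = ()
    spikes_per_electrode_in_burst: float = 10.0
    burst_envelope_ms: float = 4.0
    hub_offset_spread_ms: float = 80.0
    burst_vigor_sigma: float = 0.4
    condition_factor: float = 1.0  # delta
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_electrodes < 1 or self.duration_s <= 0:
            raise ParameterError("need n_electrodes >= 1 and duration_s > 0")
        for name in (
            "background_rate_hz",
            "burst_rate_per_min",
            "spikes_per_electrode_in_burst",
            "burst_envelope_ms",
            "hub_offset_spread_ms",
            "burst_vigor_sigma",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.condition_factor > 0:
            raise ParameterError("condition_factor must be > 0")

    @property
    def electrode_ids(self) -> tuple[str, ...]:
        if self.n_electrodes == 60:
            return MEA60_LAYOUT
        return tuple(f"e{i + 1}" for i in range(self.n_electrodes))


def chain_network(
    electrode_ids: Sequence[str] | None = None,
    n_chains: int = 6,
    chain_delays_ms: Sequence[float] = (7, 9, 11, 13, 15, 17),
    transmission_prob: float = 0.85,
    jitter_ms: float = 0.5,
) -> tuple[tuple[str, ...], tuple[PlantedEdge, ...]]:
    """Partition the electrodes into hub-headed propagation chains.

    Chain ``c`` uses a uniform per-hop delay ``chain_delays_ms[c]``; the first
    electrode of each chain is its hub.  The delay values are chosen so that
    no cumulative (multi-hop) lag lands near the 50 ms synchrony boundary,
    keeping the planted ground truth unambiguous.

    Returns ``(hub_electrodes, planted_edges)``.
    """
    if electrode_ids is None:
        electrode_ids = MEA60_LAYOUT
    ids = [str(e) for e in electrode_ids]
    if n_chains > len(ids):
        raise ParameterError("more chains than electrodes")
    if len(chain_delays_ms) < n_chains:
        raise ParameterError("need one delay per chain")
    chains: list[list[str]] = [[] for _ in range(n_chains)]
    for i, eid in enumerate(ids):
        chains[i % n_chains].append(eid)
    hubs = tuple(chain[0] for chain in chains)
    edges = []
    for chain, d in zip(chains, chain_delays_ms):
        for a, b in zip(chain, chain[1:]):
            edges.append(
                PlantedEdge(
                    source=a,
                    target=b,
                    delay_ms=float(d),
                    transmission_prob=transmission_prob,
                    jitter_ms=jitter_ms,
                )
            )
    return hubs, tuple(edges)


def default_config(seed: int = 0, condition_factor: float = 1.0) -> SyntheticConfig:
    """Intact-culture defaults with the standard chain network planted."""
    hubs, edges = chain_network()
    return SyntheticConfig(
        hub_electrodes=hubs,
        planted_edges=edges,
        condition_factor=condition_factor,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the generator actually planted, for pipeline validation."""

    burst_onsets_s: np.ndarray
    planted_edges: tuple[PlantedEdge, ...]
    detectable_pairs: dict[tuple[str, str], float]
    expected_background_spikes: float
    expected_n_bursts: float


def detectable_pairs(
    edges: Sequence[PlantedEdge], max_delay_ms: float = 50.0
) -> dict[tuple[str, str], float]:
    """All time-locked ordered pairs with cumulative delay <= max_delay_ms.

    Because edge delays compose along propagation paths, every ancestor ->
    descendant pair whose summed delay stays within the synchrony horizon is
    a real, recoverable time-locked relation; this is the ground-truth edge
    set a delay-synchrony detector should find.  Where several paths link a
    pair, the smallest cumulative delay is recorded.
    """
    out_edges: dict[str, list[PlantedEdge]] = {}
    for e in edges:
        out_edges.setdefault(e.source, []).append(e)
    found: dict[tuple[str, str], float] = {}
    for start in sorted(out_edges):
        # bounded DFS; cumulative delay grows by >= 1 ms per hop so it halts
        stack = [(start, 0.0)]
        while stack:
            node, acc = stack.pop()
            for e in out_edges.get(node, []):
                total = acc + e.delay_ms
                if total > max_delay_ms:
                    continue
                key = (start, e.target)
                if key not in found or total < found[key]:
                    found[key] = total
                stack.append((e.target, total))
    return found


def generate_recording(c: SyntheticConfig) -> tuple[SpikeTrainSet, GroundTruth]:
    """Simulate one recording; deterministic under (config, seed)."""
    rng = np.random.default_rng(c.seed)
    ids = c.electrode_ids
    delta = c.condition_factor
    known = set(ids)
    for h in c.hub_electrodes:
        if h not in known:
            raise ParameterError(f"hub electrode {h!r} not in layout")
    for e in c.planted_edges:
        if e.source not in known or e.target not in known:
            raise ParameterError(f"planted edge {e.source}->{e.target} not in layout")

    spikes: dict[str, list[float]] = {eid: [] for eid in ids}

    # network bursts
    rate_per_s = c.burst_rate_per_min * delta / 60.0
    n_bursts = rng.poisson(rate_per_s * c.duration_s)
    onsets = np.sort(rng.uniform(0.0, c.duration_s, size=n_bursts))
    out_edges: dict[str, list[PlantedEdge]] = {}
    for e in c.planted_edges:
        out_edges.setdefault(e.source, []).append(e)

    for onset in onsets:
        vigor = (
            rng.lognormal(mean=0.0, sigma=c.burst_vigor_sigma)
            if c.burst_vigor_sigma > 0
            else 1.0
        )
        mean_count = c.spikes_per_electrode_in_burst * delta * vigor
        # activation times in ms relative to onset, earliest-parent semantics
        activation: dict[str, float] = {}
        frontier: list[tuple[float, str]] = []
        for h in c.hub_electrodes:
            t = float(rng.uniform(0.0, c.hub_offset_spread_ms))
            activation[h] = t
            frontier.append((t, h))
        frontier.sort()
        while frontier:
            t_node, node = frontier.pop(0)
            for e in out_edges.get(node, []):
                if e.target in activation:
                    continue
                if rng.random() < e.transmission_prob * delta:
                    t = t_node + e.delay_ms
                    if e.jitter_ms > 0:
                        t += float(rng.normal(0.0, e.jitter_ms))
                    activation[e.target] = t
                    # insert keeping the frontier sorted by activation time
                    lo = 0
                    while lo < len(frontier) and frontier[lo][0] < t:
                        lo += 1
                    frontier.insert(lo, (t, e.target))
        for eid in ids:
            if eid not in activation:
                continue
            n_sp = rng.poisson(mean_count)
            if n_sp == 0:
                continue
            offs = rng.uniform(0.0, c.burst_envelope_ms, size=n_sp)
            times = onset + (activation[eid] + offs) / 1000.0
            spikes[eid].extend(times.tolist())

    # tonic background, independent of the condition factor
    if c.background_rate_hz > 0:
        for eid in ids:
            n_bg = rng.poisson(c.background_rate_hz * c.duration_s)
            spikes[eid].extend(rng.uniform(0.0, c.duration_s, size=n_bg).tolist())

    # clip, sort, deduplicate on the 0.01 ms comparison grid
    clean: dict[str, np.ndarray] = {}
    for eid in ids:
        t = np.sort(np.asarray(spikes[eid], dtype=float))
        t = t[(t >= 0.0) & (t <= c.duration_s)]
        if t.size:
            ticks = to_ticks(t)
            keep = np.concatenate(([True], np.diff(ticks) > 0))
            t = ticks[keep] / TICKS_PER_SECOND
        clean[eid] = t

    rec = SpikeTrainSet(
        electrode_ids=ids,
        spikes=clean,
        duration_s=c.duration_s,
        meta={"seed": int(c.seed), "condition_factor": float(delta)},
    )
    truth = GroundTruth(
        burst_onsets_s=onsets,
        planted_edges=c.planted_edges,
        detectable_pairs=detectable_pairs(c.planted_edges),
        expected_background_spikes=c.background_rate_hz * c.duration_s * len(ids),
        expected_n_bursts=rate_per_s * c.duration_s,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# longitudinal designs

#: condition-factor schedules emulating the study's group trajectories:
#: intact cultures stay stationary, amyloid exposure suppresses activity
#: progressively, and chronic astrocyte stimulation largely rescues it.
DEFAULT_SCHEDULES: dict[str, dict[int, float]] = {
    "Intact": {14: 1.0, 15: 1.0, 17: 1.0, 19: 1.0, 21: 1.0},
    "Ab": {14: 1.0, 15: 0.85, 17: 0.65, 19: 0.45, 21: 0.3},
    "Ab+ChR2": {14: 1.0, 15: 0.95, 17: 0.9, 19: 0.85, 21: 0.8},
}


def derive_seed(master_seed: int, group: str, div: int, replicate: int) -> int:
    """Deterministic per-recording seed: CRC-32 of "master|group|div|replicate"."""
    key = f"{master_seed}|{group}|{div}|{replicate}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def generate_longitudinal(
    schedules: Mapping[str, Mapping[int, float]] | None = None,
    replicates: int = 5,
    master_seed: int = 0,
    base_config: SyntheticConfig | None = None,
) -> tuple[RecordingBundle, dict[str, GroundTruth]]:
    """Simulate a full group x DIV study design.

    ``schedules`` maps group label -> {DIV: condition factor}; each cell gets
    ``replicates`` recordings with seeds derived from the master seed.
    Returns the bundle plus per-recording ground truth keyed by recording id.
    """
    if schedules is None:
        schedules = DEFAULT_SCHEDULES
    if base_config is None:
        base_config = default_config()
    recordings = []
    truths: dict[str, GroundTruth] = {}
    design: dict[str, dict[int, list[str]]] = {}
    for group in sorted(schedules):
        design[group] = {}
        for div in sorted(schedules[group]):
            delta = schedules[group][div]
            rec_ids = []
            for rep in range(replicates):
                seed = derive_seed(master_seed, group, div, rep)
                cfg = replace(base_config, condition_factor=delta, seed=seed)
                rec, truth = generate_recording(cfg)
                rid = f"{_slug(group)}_div{div}_r{rep}"
                rec.meta.update(
                    {"recording_id": rid, "group_label": group, "div": int(div)}
                )
                recordings.append(rec)
                truths[rid] = truth
                rec_ids.append(rid)
            design[group][int(div)] = rec_ids
    return RecordingBundle(recordings=recordings, design=design), truths


def _slug(label: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in label)
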