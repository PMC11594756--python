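# meanet

Network-burst and functional-connectivity analysis for multielectrode-array
(MEA) spike recordings of cultured neuronal networks, plus a ground-truthed
synthetic recording generator for validating every stage of the pipeline.

The package targets the standard in-vitro neurophenotyping workflow: 60
electrodes record spontaneous spikes from a hippocampal or cortical culture
for ten minutes; population events ("network bursts") are detected and
characterised; delayed spike synchrony between electrode pairs is turned into
a directed functional-connectivity graph; and groups of cultures (e.g.
control vs. amyloid-exposed vs. rescued) are compared across days in vitro
(DIV).

## The analysis

**Network bursts.** A network burst is an event in which at least 4 spikes
from at least 4 distinct electrodes fall within a 50 ms window. A window is
slid over every spike; overlapping qualifying windows are merged into one
burst. Bursts are classed by *amplitude* — the peak spike count in any 50 ms
window inside the burst — as **small** (4–100 spikes/50 ms) or **large**
(>100 spikes/50 ms). Per recording, five parameters are reported: burst rate,
mean spikes per burst, mean burst duration, mean amplitude (each split by
class), and the percentage of all spikes that fall inside burst spans.

**Connectivity.** For each ordered electrode pair (m, n), fifty cumulative
delay windows of 1..50 ms are examined: a spike on n is *synchronous with
delay* at window k if some spike on m precedes it by d ∈ (0, k] ms. The
ranking score of the pair is

  score(m→n) = (number of synchronous target spikes at k = 50 ms) / (total spikes on n),

computed on spikes inside large-burst spans. The top 5% of positive-score
ordered pairs become the edges of a directed graph; node degree (in+out),
hub nodes (degree at or above the 90th percentile, minimum 2), the hub
coefficient (mean hub degree) and the graph diameter (longest finite
shortest path, undirected) summarise the network architecture.

**Statistics.** Group differences use the tie-corrected Kruskal–Wallis test
(significance at p ≤ 0.05), fold changes are reported against each group's
DIV14 baseline, and relative qPCR expression uses the ΔΔCt method,
fold = 2^(−ΔΔCt).

**Synthetic recordings.** `meanet.synthetic` simulates recordings with known
ground truth: tonic Poisson background, hub-initiated bursts propagating
along planted directed edges with fixed delays, and a condition factor δ
that jointly scales burst rate, burst size and transmission probability
(δ = 1 intact, δ < 1 graded amyloid-like suppression).

## Worked example

```python
from meanet import (default_config, generate_recording, detect_network_bursts,
                    compute_burst_statistics, all_pair_profiles, rank_pairs,
                    build_connectivity_graph, hub_metrics)

rec, truth = generate_recording(default_config(seed=1))   # 10 min, 60 electrodes
bursts = detect_network_bursts(rec)
stats = compute_burst_statistics(rec, bursts)
print(len(bursts), sum(b.size_class == "large" for b in bursts))
print(round(stats.pct_spikes_in_bursts, 1))

graph = build_connectivity_graph(rank_pairs(all_pair_profiles(rec, bursts)))
hubs, hub_coeff, diameter = hub_metrics(graph)
print(graph.graph.number_of_edges(), len(hubs), hub_coeff, diameter)
```

prints

```
83 69
88.3
141 10 7.2 5
```

i.e. 83 network bursts of which 69 are large, 88.3% of all spikes inside
burst spans, and a 141-edge directed graph with 10 hub electrodes, a hub
coefficient of 7.2 connections and diameter 5. Of those 141 edges, all lie
in the planted time-locked pair set (`truth.detectable_pairs`, 172 pairs),
with recovered delays within 2 ms of the planted lags.

## Analysis scripts

The `analysis/` directory reproduces the full study workflow on synthetic
data: `01_simulate_cultures.py` (three groups × five DIVs × five
replicates), `02_burst_statistics.py`, `03_connectivity_graphs.py`,
`04_group_comparison.py`. Each writes tidy tables under `results/` (large
spike tables and GraphML go under `scratch/`). The same pipeline is exposed
as a CLI: `meanet simulate|bursts|graph|stats|report`.

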