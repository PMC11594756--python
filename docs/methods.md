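# Methods

This note documents the models, conventions and numerical choices behind
`meanet`, and what the synthetic validation does and does not establish
about real recordings.

## Data model and time arithmetic

Spike timestamps are stored in seconds (float64). All window arithmetic is
performed on an integer grid of 0.01 ms ticks (`round(t * 1e5)`): windows,
gaps and spans compare exactly, so detection results cannot depend on
floating-point representation. Two spikes on one electrode closer than one
tick are considered duplicates and rejected on input (the generator
deduplicates); simultaneous spikes on *different* electrodes are expected
and allowed. Minute segmentation uses half-open windows [k·60, (k+1)·60) s —
a boundary spike belongs to the later minute — except that the final segment
is closed at the recording end so segmentation conserves every spike.

## Network-burst detection

The qualifying event is ≥ `min_spikes` (4) spikes from ≥ `min_electrodes`
(4) distinct electrodes within `window_ms` (50 ms). The stricter reading of
"four spikes from different electrodes" (four *distinct* electrodes) is the
default; the looser reading is available by lowering `min_electrodes`.
Burst construction: a closed window [t, t+50 ms] is anchored at every spike;
all qualifying windows are collected; overlapping or abutting windows are
merged; each merged run is one burst whose span is clipped to the first and
last covered spike. The construction is deterministic, permutation-
invariant, and is verified exactly against an exhaustive window-scan oracle
on randomized instances.

Burst *amplitude* is the peak spike count in any 50 ms window anchored at a
spike inside the span — the spikes-per-50 ms quantity that burst raster
software plots against a threshold line; no voltage information is used or
available. Classification: amplitude ≤ 100 → small, > 100 → large. The
boundary sits at exactly 100 on the "small" side (the inclusive "4 to 100"
convention); the threshold is configurable. Burst duration is last−first
covered spike, which for a single-window burst can be < 50 ms.

Statistics per recording: small/large burst rates per minute; per-class
means of spikes per burst, duration (ms) and amplitude; and the percentage
of all recorded spikes inside burst spans. Empty classes yield NaN
(missing), never 0 — a culture with no large bursts has *no* large-burst
duration, not a zero one. A recording with zero spikes reports zero rates
and a missing percentage.

## Delay-synchrony connectivity

For an ordered pair (m, n), the fifty delay windows are **cumulative**:
window k covers delays (0, k] ms, so a target spike counted at k is counted
at every longer window and the count vector is nondecreasing — matching the
"intervals with increasing durations" construction. A target spike is
synchronous if at least one source spike strictly precedes it within the
window (zero lag does not count: a delay must be positive). Implementation:
the minimal positive gap to the immediately preceding source spike decides
the smallest qualifying k; counts are the cumulative histogram of those
gaps. A nested-loop oracle over all spike pairs and all fifty windows
verifies the counts exactly.

Choices the ranking definition leaves open, and what this package does:

* **Score.** The ratio at the longest window, k = 50 ms (under cumulative
  windows this is the maximum ratio over k). Alternatives (ratio at a fixed
  shorter k, maximal incremental ratio) would weight fast synchrony
  differently; the cumulative-maximum is the most permissive and the most
  stable on sparse trains.
* **Edge delay.** The half-rise delay: the smallest k whose count reaches
  half the k = 50 count. For a genuinely time-locked pair with lag λ the
  count vector is a step at λ, so the half-rise recovers λ; for diffuse
  synchrony it lands at the median positive lag ≤ 50 ms.
* **Spike restriction.** Profiles are computed on spikes inside *large*
  burst spans by default — large bursts are the events that recruit the
  whole network and expose its architecture — configurable to all-burst
  spans or all spikes.
* **Selection.** The top ⌈0.05 · P⌉ of the P ordered pairs with positive
  score. Zero-score pairs are never selected; the ceiling guarantees one
  edge whenever any synchrony exists. Ties break deterministically: smaller
  edge delay first, then lexicographic (source, target).
* **Hubs.** No published numeric hub criterion exists for this workflow, so
  hubs are nodes whose connection count (in+out degree) reaches the 0.90
  quantile of node degrees, with a floor of 2 connections; the hub
  coefficient is the mean hub degree. **Diameter** is the standard longest
  finite shortest-path length on the underlying undirected graph (0 for
  fewer than two nodes), computed per connected component.

## Synthetic recordings and ground truth

The generator produces the observables the pipeline measures with the
simplest sufficient mechanism — it validates the *analysis*, not neural
dynamics. Defaults describe a mature intact culture on a 60-electrode
array:

| parameter | default | meaning |
|---|---|---|
| `duration_s` | 600 | ten-minute recording session |
| `background_rate_hz` | 0.1 | tonic per-electrode Poisson spiking |
| `burst_rate_per_min` | 8 | network-burst initiation rate |
| `spikes_per_electrode_in_burst` | 10 | mean volley size per activated electrode |
| `burst_envelope_ms` | 4 | within-electrode volley spread |
| `hub_offset_spread_ms` | 80 | desynchronisation of hub onsets within a burst |
| `burst_vigor_sigma` | 0.4 | lognormal burst-to-burst size variability |
| `condition_factor` (δ) | 1.0 | joint multiplier on rate, size, transmission |

The planted network is, by default, six hub-headed chains covering all 60
electrodes, with uniform per-chain hop delays of 7, 9, 11, 13, 15 and 17 ms.
Within a burst each hub activates at a random offset, and activation
propagates edge by edge: target activation time = source activation time +
delay + N(0, jitter), succeeding with probability `transmission_prob · δ`
(0.85 at δ = 1). Delays therefore compose along chains, and the ground
truth exposed for connectivity validation is the set of **time-locked
pairs**: every ancestor→descendant pair whose cumulative delay is ≤ 50 ms
(172 pairs for the default network), with that cumulative delay as the
expected edge delay. A delay-synchrony statistic *should* report transitive
locked lags — they are physically present in the spike trains — so recovery
is scored against this set rather than against the 54 direct edges alone.
The chain delays are chosen so no cumulative lag falls in [50, 53] ms,
keeping the ground truth unambiguous under jitter at the 50 ms horizon.

Chosen study conditions in the default longitudinal design (five replicates
per cell, recordings at DIV 14, 15, 17, 19, 21): δ = 1 throughout for the
intact group; δ declining 1.0 → 0.3 for the amyloid group; δ declining only
to 0.8 for the amyloid + chronic-stimulation group. These schedules
reproduce the qualitative group contrasts the pipeline must resolve —
stationary intact activity, progressive collapse of burst-organised
spiking under amyloid (including recordings that lose burst activity
entirely at low δ, since the thresholded large-burst classification
responds steeply to the joint suppression), and intermediate, largely
preserved activity under the rescue schedule. Per-recording seeds derive
from the master seed by CRC-32 of `"master|group|DIV|replicate"`, so any
recording can be regenerated in isolation.

What the synthetic model does **not** emulate: single-electrode (non-
network) bursting, refractoriness and adaptation, electrode geometry and
distance-dependent delays, non-stationarity within a recording, recurrent
(cyclic) connectivity, and recording artifacts. Passing the planted-
recovery tests therefore shows the pipeline correctly implements its stated
definitions and recovers structure *of this generative form*; it does not
certify performance on real recordings with biological confounds.

## Statistics

Kruskal–Wallis uses the tie-corrected H and the χ² approximation with k−1
degrees of freedom (scipy); all-identical samples short-circuit to H = 0,
p = 1 (rank-degenerate case the χ² form does not cover). An exact
permutation p-value over all group relabellings is available behind a flag
for total N ≤ 12, where the χ² approximation is weakest. Null calibration
(3 groups × 8, 2000 simulations) is asserted to reject at 3–7% at α = 0.05.
Fold changes divide each (group, DIV) mean by the group's DIV14 mean; zero
or missing baselines yield missing ratios, never infinities. Post-hoc
pairwise rank tests with Holm adjustment are provided but flag-gated, since
the omnibus test is the primary published comparison. ΔΔCt follows the
closed form fold = 2^(−ΔΔCt) with the control-group mean ΔCt as reference.

## Problem sizes used in validation

The test suite and acceptance script validate at the scale the analysis is
designed for: full 60-electrode, 10-minute recordings for planted-network
recovery (3 fixed seeds); 200 randomized instances of ≤ 1000 spikes on 8–60
electrodes for exact burst-detector/oracle agreement; 100 random train
pairs for synchrony-count agreement; 20 replicates per condition for the
group-ordering checks; 2000 simulations for test calibration. The
longitudinal drivers use 5 replicates per (group, DIV) cell, matching the
per-group culture counts typical of such studies.

## Known limitations

* The ranking score is one of several defensible readings of "ratio-based
  ranking"; alternatives are configurable but not the tested default.
* The top-5% selection fixes the edge count at ⌈0.05 · P⌉, so recall
  against a planted set larger than that is structurally capped — the
  default ground truth (172 pairs) slightly exceeds the typical selection
  size (~140–150), which is visible as recall ≈ 0.82–0.88 with precision
  ≈ 1.0.
* Graph "diameter" is the standard shortest-path definition; workflows that
  use the word loosely for network extent (node/edge counts) will read
  different numbers from the same graph.
* The exact-permutation Kruskal–Wallis enumerates all N! relabellings and
  is only practical for N ≤ 12.
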