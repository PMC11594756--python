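import math

import networkx as nx
import numpy as np
import pytest

from meanet import (
    PairSyncProfile,
    build_connectivity_graph,
    detect_network_bursts,
    hub_metrics,
    pair_sync_profile,
    rank_pairs,
)
from meanet.connectivity import (
    RESTRICT_NONE,
    ConnectivityGraph,
    _sync_counts,
    all_pair_profiles,
)

from conftest import make_recording
from oracles import oracle_diameter, oracle_sync_counts


def profile(counts, n_target):
    return PairSyncProfile(
        source="m", target="n", counts=np.asarray(counts), n_target_spikes=n_target
    )


class TestPairSync:
    def test_shifted_train_rises_exactly_at_the_shift(self):
        # target = source + 5 ms: ratios 0 below 5 ms, 1 from 5 ms on
        src = [0.1, 0.2, 0.3, 0.4]
        tgt = [t + 0.005 for t in src]
        rec = make_recording({"m": src, "n": tgt}, duration_s=1.0)
        p = pair_sync_profile(rec, [], "m", "n", restrict=RESTRICT_NONE)
        assert np.all(p.ratios[:4] == 0)
        assert np.all(p.ratios[4:] == 1.0)
        assert p.best_delay_ms == 5

    def test_empty_source_gives_zero_profile(self):
        rec = make_recording({"m": [], "n": [0.1, 0.2]}, duration_s=1.0)
        p = pair_sync_profile(rec, [], "m", "n", restrict=RESTRICT_NONE)
        assert p.score == 0 and np.all(p.counts == 0)

    def test_empty_target_gives_zero_score_not_error(self):
        rec = make_recording({"m": [0.1], "n": []}, duration_s=1.0)
        p = pair_sync_profile(rec, [], "m", "n", restrict=RESTRICT_NONE)
        assert p.score == 0

    def test_self_pair_rejected(self):
        rec = make_recording({"m": [0.1]}, duration_s=1.0)
        with pytest.raises(ValueError):
            pair_sync_profile(rec, [], "m", "m")

    def test_simultaneous_spikes_are_not_synchronous(self):
        rec = make_recording({"m": [0.1], "n": [0.1]}, duration_s=1.0)
        p = pair_sync_profile(rec, [], "m", "n", restrict=RESTRICT_NONE)
        assert np.all(p.counts == 0)

    def test_matches_nested_loop_oracle_on_random_trains(self, rng):
        for _ in range(30):
            src = np.unique(rng.integers(0, 20_000, size=rng.integers(0, 60)))
            tgt = np.unique(rng.integers(0, 20_000, size=rng.integers(1, 60)))
            counts = _sync_counts(src, tgt, 50)
            assert np.array_equal(counts, oracle_sync_counts(src, tgt))
            assert np.all(np.diff(counts) >= 0)  # cumulative windows

    def test_profiles_restricted_to_large_burst_spans(self, intact_recording, intact_bursts):
        rec, _ = intact_recording
        profiles = all_pair_profiles(rec, intact_bursts)
        n_in_burst = {p.target: p.n_target_spikes for p in profiles}
        for eid, n in n_in_burst.items():
            assert n <= rec.spikes[eid].size


class TestRanking:
    def test_distinct_scores_sorted_descending(self):
        ps = [profile([0] * 49 + [k], 10) for k in (3, 9, 6)]
        ranked = rank_pairs(ps)
        assert [p.counts[-1] for p in ranked] == [9, 6, 3]

    def test_tie_broken_by_smaller_delay_then_lexicographic(self):
        slow = PairSyncProfile("a", "b", [0] * 6 + [5] * 44, 10)
        fast = PairSyncProfile("c", "d", [0] * 2 + [5] * 48, 10)
        assert slow.score == fast.score == 0.5
        assert [p.source for p in rank_pairs([slow, fast])] == ["c", "a"]
        twin = PairSyncProfile("a", "a2", [0] * 2 + [5] * 48, 10)
        assert [p.source for p in rank_pairs([fast, twin])] == ["a", "c"]

    def test_order_matches_independent_sort(self, rng):
        ps = []
        for i in range(40):
            counts = np.sort(rng.integers(0, 20, size=50))
            ps.append(PairSyncProfile(f"m{i}", f"n{i}", counts, 20))
        ranked = rank_pairs(ps)
        keys = [(-p.score, p.best_delay_ms, p.source, p.target) for p in ranked]
        assert keys == sorted(keys)


class TestGraph:
    def test_all_zero_scores_give_empty_graph(self):
        ps = [profile([0] * 50, 10) for _ in range(20)]
        g = build_connectivity_graph(rank_pairs(ps))
        assert g.graph.number_of_edges() == 0
        assert hub_metrics(g) == ([], pytest.approx(math.nan, nan_ok=True), 0)

    def test_top_five_percent_of_100_positive_pairs_is_5_edges(self):
        ps = [
            PairSyncProfile(f"m{i}", f"n{i}", [0] * 49 + [i + 1], 200)
            for i in range(100)
        ]
        g = build_connectivity_graph(rank_pairs(ps))
        assert g.graph.number_of_edges() == 5
        assert {u for u, _ in g.graph.edges} == {f"m{i}" for i in range(95, 100)}

    def test_ceiling_rule_63_positive_pairs_gives_4_edges(self):
        ps = [
            PairSyncProfile(f"m{i}", f"n{i}", [0] * 49 + [i + 1], 100)
            for i in range(63)
        ]
        g = build_connectivity_graph(rank_pairs(ps))
        assert g.graph.number_of_edges() == 4

    def test_selection_invariant_to_input_permutation(self, rng):
        ps = [
            PairSyncProfile(f"m{i}", f"n{i}", np.sort(rng.integers(0, 50, 50)), 60)
            for i in range(80)
        ]
        g1 = build_connectivity_graph(rank_pairs(ps))
        shuffled = list(ps)
        rng.shuffle(shuffled)
        g2 = build_connectivity_graph(rank_pairs(shuffled))
        assert sorted(g1.graph.edges) == sorted(g2.graph.edges)


class TestHubMetrics:
    def test_star_graph(self):
        g = nx.DiGraph()
        for leaf in "abcdef":
            g.add_edge("hub", leaf, delay_ms=3, score=1.0)
        hubs, coeff, diameter = hub_metrics(ConnectivityGraph(g))
        assert hubs == ["hub"] and coeff == 6 and diameter == 2

    def test_diameter_matches_apsp_oracle_on_random_graphs(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(
                20, 0.12, seed=int(rng.integers(0, 2**31)), directed=True
            )
            cg = ConnectivityGraph(nx.DiGraph(g.edges))
            _, _, diameter = hub_metrics(cg)
            assert diameter == oracle_diameter(list(g.edges), list(g.nodes))

    def test_hub_coefficient_is_mean_hub_degree(self, intact_recording, intact_bursts):
        rec, _ = intact_recording
        g = build_connectivity_graph(rank_pairs(all_pair_profiles(rec, intact_bursts)))
        hubs, coeff, _ = hub_metrics(g)
        degs = g.degrees
        assert hubs and coeff == pytest.approx(np.mean([degs[h] for h in hubs]))
        assert all(degs[h] >= 2 for h in hubs)


class TestStructuralInvariants:
    def test_removing_an_electrode_removes_its_edges(self, intact_recording, intact_bursts):
        from meanet import SpikeTrainSet

        rec, _ = intact_recording
        g = build_connectivity_graph(rank_pairs(all_pair_profiles(rec, intact_bursts)))
        victim = next(iter(g.graph.nodes))
        stripped = SpikeTrainSet(
            electrode_ids=rec.electrode_ids,
            spikes={
                e: (np.empty(0) if e == victim else t) for e, t in rec.spikes.items()
            },
            duration_s=rec.duration_s,
        )
        bursts2 = detect_network_bursts(stripped)
        g2 = build_connectivity_graph(rank_pairs(all_pair_profiles(stripped, bursts2)))
        assert victim not in g2.graph.nodes
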