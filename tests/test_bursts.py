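import math

import numpy as np
import pytest

from meanet import (
    BurstDetectionParams,
    NetworkBurst,
    classify_burst,
    compute_burst_statistics,
    detect_network_bursts,
    generate_longitudinal,
)
from meanet.bursts import LARGE, SMALL, ParameterError, longitudinal_summary
from meanet.spikeio import to_ticks

from conftest import make_recording, random_recording
from oracles import oracle_detect_bursts


def as_tuples(bursts):
    return [
        (
            int(to_ticks(b.start_s)),
            int(to_ticks(b.end_s)),
            b.total_spikes,
            b.n_electrodes,
            b.peak_rate,
            b.size_class,
        )
        for b in bursts
    ]


def oracle_tuples(oracle_bursts):
    return [
        (
            b["start_ticks"],
            b["end_ticks"],
            b["total_spikes"],
            b["n_electrodes"],
            b["peak_rate"],
            b["size_class"],
        )
        for b in oracle_bursts
    ]


class TestDetection:
    def test_empty_recording(self):
        rec = make_recording({"e1": []}, duration_s=10)
        assert detect_network_bursts(rec) == []

    def test_minimal_qualifying_event(self):
        rec = make_recording(
            {"e1": [0.000], "e2": [0.010], "e3": [0.020], "e4": [0.030]},
            duration_s=10,
        )
        (b,) = detect_network_bursts(rec)
        assert b.start_s == pytest.approx(0.0)
        assert b.end_s == pytest.approx(0.030)
        assert b.total_spikes == 4 and b.n_electrodes == 4
        assert b.size_class == SMALL

    def test_single_electrode_fails_distinct_requirement(self):
        rec = make_recording({"e1": [0.0, 0.01, 0.02, 0.03]}, duration_s=10)
        assert detect_network_bursts(rec) == []

    def test_relaxed_min_electrodes_reading(self):
        rec = make_recording(
            {"e1": [0.0, 0.01, 0.02], "e2": [0.03]}, duration_s=10
        )
        assert detect_network_bursts(rec) == []
        relaxed = BurstDetectionParams(min_electrodes=2)
        assert len(detect_network_bursts(rec, relaxed)) == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            BurstDetectionParams(window_ms=0)
        with pytest.raises(ParameterError):
            BurstDetectionParams(min_spikes=0)
        with pytest.raises(ParameterError):
            BurstDetectionParams(min_spikes=10, large_threshold=5)

    @pytest.mark.parametrize("bursty", [False, True])
    def test_matches_window_scan_oracle_on_random_instances(self, rng, bursty):
        params = BurstDetectionParams()
        for _ in range(12):
            rec = random_recording(
                rng,
                n_electrodes=int(rng.integers(8, 16)),
                n_spikes=500,
                duration_s=10.0,
                bursty=bursty,
            )
            assert as_tuples(detect_network_bursts(rec, params)) == oracle_tuples(
                oracle_detect_bursts(rec, params)
            )

    def test_bursts_disjoint_and_ordered(self, intact_bursts):
        for a, b in zip(intact_bursts, intact_bursts[1:]):
            assert a.end_s < b.start_s

    def test_lowering_thresholds_never_loses_bursts(self, rng):
        rec = random_recording(rng, 10, 400, 10.0, bursty=True)
        base = len(detect_network_bursts(rec, BurstDetectionParams()))
        fewer_spikes = len(
            detect_network_bursts(rec, BurstDetectionParams(min_spikes=3, min_electrodes=3))
        )
        assert fewer_spikes >= base

    def test_raising_large_threshold_never_adds_large_bursts(self, rng):
        rec = random_recording(rng, 12, 600, 5.0, bursty=True)
        n_large = lambda thr: sum(
            b.size_class == LARGE
            for b in detect_network_bursts(
                rec, BurstDetectionParams(large_threshold=thr)
            )
        )
        counts = [n_large(t) for t in (10, 50, 100, 200)]
        assert counts == sorted(counts, reverse=True)


class TestClassification:
    @pytest.mark.parametrize(
        "peak,expected", [(4, SMALL), (100, SMALL), (101, LARGE)]
    )
    def test_boundary(self, peak, expected):
        b = NetworkBurst(
            start_s=0,
            end_s=0.05,
            total_spikes=peak,
            per_electrode_counts={},
            n_electrodes=4,
            peak_rate=peak,
        )
        assert classify_burst(b, BurstDetectionParams()) == expected

    def test_threshold_configurable(self):
        b = NetworkBurst(0, 0.05, 30, {}, 4, peak_rate=30)
        assert classify_burst(b, BurstDetectionParams(large_threshold=20)) == LARGE


class TestStatistics:
    def test_all_spikes_in_bursts_gives_100pct(self):
        rec = make_recording(
            {"e1": [0.0], "e2": [0.01], "e3": [0.02], "e4": [0.03]}, duration_s=60
        )
        bursts = detect_network_bursts(rec)
        stats = compute_burst_statistics(rec, bursts)
        assert stats.pct_spikes_in_bursts == pytest.approx(100.0)

    def test_no_bursts_gives_0pct(self):
        rec = make_recording({"e1": [1.0, 30.0]}, duration_s=60)
        stats = compute_burst_statistics(rec, [])
        assert stats.pct_spikes_in_bursts == pytest.approx(0.0)
        assert math.isnan(stats.mean_spikes_small)  # missing, not zero

    def test_zero_spikes_reports_missing_pct(self):
        rec = make_recording({"e1": []}, duration_s=60)
        stats = compute_burst_statistics(rec, [])
        assert stats.n_small_per_min == 0 and math.isnan(stats.pct_spikes_in_bursts)

    def test_hand_constructed_two_burst_fixture(self):
        # one small burst (10 spikes / 30 ms), one large (120 spikes / 40 ms),
        # 30 stray spikes, in 600 s: rates 0.1/min each, pct = 100*130/160
        spikes = {f"e{i}": [] for i in range(8)}
        for i in range(10):  # small burst at t=10 s
            spikes[f"e{i % 8}"].append(10.0 + i * 0.003)
        for i in range(120):  # large burst at t=20 s
            spikes[f"e{i % 8}"].append(20.0 + i * 0.04 / 120)
        for i in range(30):  # stray background, widely separated
            spikes[f"e{i % 8}"].append(40.0 + i * 15.0)
        rec = make_recording(spikes, duration_s=600)
        bursts = detect_network_bursts(rec)
        assert [b.size_class for b in bursts] == [SMALL, LARGE]
        stats = compute_burst_statistics(rec, bursts)
        assert stats.n_small_per_min == pytest.approx(0.1)
        assert stats.n_large_per_min == pytest.approx(0.1)
        assert stats.pct_spikes_in_bursts == pytest.approx(100 * 130 / 160)
        assert stats.mean_spikes_small == pytest.approx(10)
        assert stats.mean_spikes_large == pytest.approx(120)

    def test_conservation_on_random_inputs(self, rng):
        from meanet.bursts import spikes_in_burst_spans

        for bursty in (False, True):
            rec = random_recording(rng, 10, 300, 8.0, bursty=bursty)
            bursts = detect_network_bursts(rec)
            inside = spikes_in_burst_spans(rec, bursts)
            assert 0 <= inside <= rec.n_spikes
            stats = compute_burst_statistics(rec, bursts)
            assert 0 <= stats.pct_spikes_in_bursts <= 100


@pytest.fixture(scope="module")
def small_bundle():
    bundle, _ = generate_longitudinal(
        schedules={"Intact": {14: 1.0, 21: 1.0}, "Ab": {14: 1.0, 21: 0.3}},
        replicates=2,
        master_seed=11,
    )
    return bundle


class TestLongitudinal:
    def test_one_row_per_recording_with_unit_baseline_folds(self, small_bundle):
        df = longitudinal_summary(small_bundle)
        assert len(df) == 8
        base = df[(df["group"] == "Intact") & (df["div"] == 14)]
        # baseline fold changes average to 1 by construction
        assert base["fold_pct_spikes_in_bursts"].mean() == pytest.approx(1.0)

    def test_suppressed_group_loses_burst_spikes(self, small_bundle):
        df = longitudinal_summary(small_bundle)
        ab = df[df["group"] == "Ab"]
        assert (
            ab[ab["div"] == 21]["pct_spikes_in_bursts"].mean()
            < ab[ab["div"] == 14]["pct_spikes_in_bursts"].mean()
        )

    def test_rows_match_independent_per_recording_statistics(self, small_bundle):
        df = longitudinal_summary(small_bundle).set_index("recording_id")
        for _, _, rec in small_bundle.iter_design():
            stats = compute_burst_statistics(rec, detect_network_bursts(rec))
            row = df.loc[rec.meta["recording_id"]]
            assert row["pct_spikes_in_bursts"] == pytest.approx(
                stats.pct_spikes_in_bursts, nan_ok=True
            )
            assert row["n_large_per_min"] == pytest.approx(stats.n_large_per_min)

    def test_missing_baseline_leaves_folds_missing(self):
        bundle, _ = generate_longitudinal(
            schedules={"Late": {21: 1.0}}, replicates=1, master_seed=3
        )
        df = longitudinal_summary(bundle)
        assert df["fold_pct_spikes_in_bursts"].isna().all()
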