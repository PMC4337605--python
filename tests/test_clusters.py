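"""Decoration classification, cluster runs, neighbor table, growth events."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from helixafm import (
    ClusterInterval,
    PeakRecord,
    classify_decoration,
    detect_growth_events,
    direction_preference,
    find_clusters,
    half_pitches,
    neighbor_pitch_table,
    neighbor_rows,
)
from helixafm.clusters import GrowthEvent
from helixafm.config import STATE_DECORATED
from helixafm.helixmetrics import HalfHelix


def helix(height, pitch=36.8):
    a = PeakRecord(0, (0, 0), 0.0, height)
    b = PeakRecord(0, (pitch, 0), pitch, height)
    return HalfHelix(pitch, height, a, b)


def helices_from(heights, pitches=None):
    pitches = pitches or [36.8] * len(heights)
    return [helix(h, p) for h, p in zip(heights, pitches)]


class TestClassifyDecoration:
    @pytest.mark.parametrize("h,state", [(10.6, "decorated"), (8.6, "bare"), (9.6, "decorated")])
    def test_threshold_rule(self, h, state):
        assert classify_decoration([helix(h)]) == [state]

    def test_error_rate_matches_gaussian_overlap(self):
        rng = np.random.default_rng(4)
        n = 20000
        bare = rng.normal(8.6, 0.8, n)
        dec = rng.normal(10.6, 1.0, n)
        bare_wrong = np.mean(np.array(classify_decoration(helices_from(bare))) == "decorated")
        dec_wrong = np.mean(np.array(classify_decoration(helices_from(dec))) == "bare")
        exp_bare = norm.sf(9.6, 8.6, 0.8)  # P(bare height >= 9.6)
        exp_dec = norm.cdf(9.6, 10.6, 1.0)  # P(decorated height < 9.6)
        for got, exp in [(bare_wrong, exp_bare), (dec_wrong, exp_dec)]:
            assert abs(got - exp) < 3 * np.sqrt(exp * (1 - exp) / n)


class TestFindClusters:
    def test_all_bare_empty(self):
        assert find_clusters(["bare"] * 6) == []

    def test_run_length_example(self):
        states = ["bare", "decorated", "decorated", "bare", "decorated"]
        spans = [(c.first, c.last) for c in find_clusters(states)]
        assert spans == [(1, 2), (4, 4)]

    def test_exhaustive_vs_brute_force_runs(self):
        for bits in itertools.product([0, 1], repeat=12):
            states = ["decorated" if b else "bare" for b in bits]
            got = [(c.first, c.last) for c in find_clusters(states)]
            # brute-force run enumeration
            expected, start = [], None
            for i, b in enumerate(bits + (0,)):
                if b and start is None:
                    start = i
                elif not b and start is not None:
                    expected.append((start, i - 1))
                    start = None
            assert got == expected


class TestNeighborTable:
    def make(self, states, pitches):
        hh = helices_from([10.6 if s == "D" else 8.6 for s in states], pitches)
        for h, s in zip(hh, states):
            h.state = STATE_DECORATED if s == "D" else "bare"
        clusters = find_clusters([h.state for h in hh])
        return clusters, hh

    def test_positions_on_both_sides(self):
        states = "BBBDDDBBB"
        pitches = [36.5, 36.6, 28.8, 26.9, 26.9, 26.9, 37.3, 35.4, 36.7]
        clusters, hh = self.make(states, pitches)
        rows = neighbor_rows(clusters, hh, "pointed_at_start")
        got = {r["position"]: r["pitch_nm"] for r in rows}
        assert got == {"P1": 28.8, "P2": 36.6, "B1": 37.3, "B2": 35.4}

    def test_polarity_flip_swaps_sides(self):
        states = "BBBDDDBBB"
        pitches = [36.5, 36.6, 28.8, 26.9, 26.9, 26.9, 37.3, 35.4, 36.7]
        clusters, hh = self.make(states, pitches)
        rows = neighbor_rows(clusters, hh, "pointed_at_end")
        got = {r["position"]: r["pitch_nm"] for r in rows}
        assert got["P1"] == 37.3 and got["B1"] == 28.8

    def test_cluster_at_filament_end_excludes_missing_side(self):
        states = "DDBBB"
        clusters, hh = self.make(states, [26.9, 26.9, 37.3, 35.4, 36.5])
        rows = neighbor_rows(clusters, hh, "pointed_at_start")
        positions = [r["position"] for r in rows]
        assert "P1" not in positions and "P2" not in positions
        assert set(positions) == {"B1", "B2"}

    def test_all_bare_empty_table(self):
        clusters, hh = self.make("BBBBB", [36.8] * 5)
        assert neighbor_rows(clusters, hh, "pointed_at_start") == []
        assert neighbor_pitch_table([]).empty

    def test_unknown_polarity_rejected(self):
        clusters, hh = self.make("BDDB", [36.8] * 4)
        with pytest.raises(ValueError):
            neighbor_rows(clusters, hh, "unknown")


def spans_to_clusters(spans_by_frame):
    return [
        [ClusterInterval(f, a, b) for a, b in spans] for f, spans in enumerate(spans_by_frame)
    ]


class TestGrowthEvents:
    def test_one_pointed_gain(self):
        events = detect_growth_events(
            spans_to_clusters([[(5, 8)], [(4, 8)]]), "pointed_at_start"
        )
        assert len(events) == 1
        assert events[0].direction == "pointed"

    def test_two_pointed_one_barbed(self):
        events = detect_growth_events(
            spans_to_clusters([[(5, 8)], [(3, 9)]]), "pointed_at_start"
        )
        dirs = sorted(ev.direction for ev in events)
        assert dirs == ["barbed", "pointed", "pointed"]

    def test_polarity_flip(self):
        events = detect_growth_events(
            spans_to_clusters([[(5, 8)], [(4, 8)]]), "pointed_at_end"
        )
        assert events[0].direction == "barbed"

    def test_nucleation_not_growth(self):
        events = detect_growth_events(
            spans_to_clusters([[], [(3, 5)]]), "pointed_at_start"
        )
        assert events == []

    def test_losses_ignored(self):
        events = detect_growth_events(
            spans_to_clusters([[(3, 9)], [(5, 8)]]), "pointed_at_start"
        )
        assert events == []

    def test_cluster_identity_by_overlap(self):
        events = detect_growth_events(
            spans_to_clusters([[(2, 3), (8, 9)], [(1, 3), (8, 10)]]),
            "pointed_at_start",
        )
        assert len(events) == 2
        by_cluster = {ev.cluster_id: ev.direction for ev in events}
        assert sorted(by_cluster.values()) == ["barbed", "pointed"]


class TestDirectionPreference:
    def test_all_pointed(self):
        evs = [GrowthEvent(0, 0, "pointed") for _ in range(10)]
        out = direction_preference(evs)
        assert out["fraction_pointed"] == 1.0

    def test_even_split_ci_spans_half(self):
        evs = [GrowthEvent(0, 0, d) for d in ["pointed"] * 5 + ["barbed"] * 5]
        out = direction_preference(evs)
        assert out["fraction_pointed"] == 0.5
        assert out["ci_low"] < 0.5 < out["ci_high"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            direction_preference([])

    def test_clopper_pearson_coverage_at_07(self):
        # Monte-Carlo coverage of the exact 95% interval
        rng = np.random.default_rng(9)
        n, reps, covered = 50, 400, 0
        for _ in range(reps):
            k = rng.binomial(n, 0.7)
            evs = [GrowthEvent(0, 0, "pointed")] * k + [GrowthEvent(0, 0, "barbed")] * (n - k)
            out = direction_preference(evs)
            covered += out["ci_low"] <= 0.7 <= out["ci_high"]
        assert 0.90 <= covered / reps <= 1.0
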