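"""Bottom-up segmentation, classification, flanks and call building."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cghindel.probes import ProbeMap, RatioProfile
from cghindel.segment import (
    AMPLIFICATION,
    DELETION,
    NORMAL,
    CallingParameters,
    call_indels,
    classify_and_filter,
    find_flanking_probes,
    segment_profile,
)

from conftest import make_profile
from oracles import least_squares_three_segments


class TestSegmentProfile:
    def test_constant_chromosome_collapses_to_one_segment(self):
        profile = make_profile(np.zeros(50))
        segs = segment_profile(profile)
        assert len(segs) == 1
        assert (segs[0].first_probe, segs[0].last_probe) == (0, 49)

    def test_default_merge_alpha_is_published_value(self):
        import inspect

        assert inspect.signature(segment_profile).parameters["merge_alpha"].default == 0.05

    def test_planted_region_boundaries_match_least_squares_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 0.2, 20)
        x[8:13] += -3.0
        profile = make_profile(x)
        call = call_indels(profile)[0]
        pm = profile.probe_map
        bounds = (pm.index_of(call.left_bp_probe), pm.index_of(call.right_bp_probe))
        assert bounds == (8, 12)
        assert least_squares_three_segments(x) == bounds

    def test_partition_and_mean_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.5, 200)
        profile = make_profile(x)
        segs = segment_profile(profile)
        covered = []
        for s in segs:
            covered.extend(range(s.first_probe, s.last_probe + 1))
            assert s.mean_log2 == pytest.approx(x[s.first_probe : s.last_probe + 1].mean())
        assert covered == list(range(200))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-4, 4, allow_nan=False), min_size=1, max_size=60),
           st.integers(0, 10_000))
    def test_partition_property(self, values, salt):
        x = np.asarray(values)
        profile = make_profile(x)
        segs = sorted(segment_profile(profile), key=lambda s: s.first_probe)
        assert segs[0].first_probe == 0
        assert segs[-1].last_probe == len(x) - 1
        for a, b in zip(segs, segs[1:]):
            assert b.first_probe == a.last_probe + 1

    def test_single_probe_chromosome(self):
        profile = make_profile([0.3])
        segs = segment_profile(profile)
        assert len(segs) == 1 and segs[0].n_probes == 1

    def test_chromosome_order_invariance(self):
        rng = np.random.default_rng(7)
        xa = rng.normal(0, 0.3, 60)
        xa[20:26] -= 3
        xb = rng.normal(0, 0.3, 40)
        xb[5:9] += 1.5

        def build(order):
            frames = []
            for chrom, x in order:
                starts = 1 + 100 * np.arange(len(x))
                frames.append(pd.DataFrame({
                    "probe_id": [f"{chrom}_{i}" for i in range(len(x))],
                    "chromosome": chrom, "start": starts, "end": starts + 49,
                    "region": "center",
                }))
            pm = ProbeMap(pd.concat(frames, ignore_index=True))
            ratios = np.concatenate([x for _, x in order])
            return RatioProfile("t", pm, ratios, normalized=True)

        calls_ab = call_indels(build([("a", xa), ("b", xb)]))
        calls_ba = call_indels(build([("b", xb), ("a", xa)]))
        key = lambda c: (c.chromosome, c.start, c.end, c.kind)  # noqa: E731
        assert sorted(map(key, calls_ab)) == sorted(map(key, calls_ba))


class TestClassifyAndFilter:
    def _segments(self, profile):
        return segment_profile(profile)

    def test_strong_negative_segment_is_deletion(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.2, 30)
        x[10:15] = -2.5 + rng.normal(0, 0.05, 5)
        profile = make_profile(x)
        labeled = classify_and_filter(profile, self._segments(profile))
        kinds = {s.label for s in labeled}
        deletion = [s for s in labeled if s.label == DELETION]
        assert len(deletion) == 1
        assert deletion[0].p_value <= 0.01
        assert (deletion[0].first_probe, deletion[0].last_probe) == (10, 14)
        assert kinds == {DELETION, NORMAL}

    def test_two_probe_deletion_exception(self):
        x = np.zeros(20) + np.linspace(-0.1, 0.1, 20)
        x[8], x[9] = -2.4, -2.6
        profile = make_profile(x)
        labeled = classify_and_filter(profile, self._segments(profile))
        deletion = [s for s in labeled if s.label == DELETION]
        assert len(deletion) == 1 and deletion[0].n_probes == 2

    def test_two_probe_above_cutoff_dropped(self):
        x = np.zeros(20) + np.linspace(-0.1, 0.1, 20)
        x[8], x[9] = -1.9, -1.8  # aberrant but above the 2-probe cutoff
        profile = make_profile(x)
        labeled = classify_and_filter(profile, self._segments(profile))
        assert all(s.label == NORMAL for s in labeled)

    def test_zero_mean_segment_is_normal(self):
        profile = make_profile(np.zeros(30))
        labeled = classify_and_filter(profile, self._segments(profile))
        assert [s.label for s in labeled] == [NORMAL]

    def test_amplification_cutoff(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.2, 40)
        x[12:20] = 1.5 + rng.normal(0, 0.1, 8)
        profile = make_profile(x)
        labeled = classify_and_filter(profile, self._segments(profile))
        amps = [s for s in labeled if s.label == AMPLIFICATION]
        assert len(amps) == 1
        assert (amps[0].first_probe, amps[0].last_probe) == (12, 19)

    def test_threshold_monotonicity_for_amplifications(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.2, 300)
        for lo in (30, 120, 210):
            x[lo : lo + 5] = rng.normal(0.95, 0.1, 5)  # near-threshold amps
        profile = make_profile(x)

        def amp_spans(cutoff):
            params = CallingParameters(amplification_cutoff=cutoff)
            calls = call_indels(profile, params=params)
            return {(c.start, c.end) for c in calls if c.kind == AMPLIFICATION}

        strict = amp_spans(1.0)
        relaxed = amp_spans(0.8)
        assert strict <= relaxed


class TestFlanks:
    def _deletion_profile(self, shoulder):
        # deletion at probes 10..14, then the given outward shoulder values
        x = np.zeros(30)
        x[10:15] = -2.9
        x[15 : 15 + len(shoulder)] = shoulder
        return make_profile(x)

    def _one_call(self, profile, params=CallingParameters()):
        calls = call_indels(profile, params=params)
        assert len(calls) == 1
        return calls[0]

    def test_clean_neighbors_flank_adjacent(self):
        profile = self._deletion_profile([])
        call = self._one_call(profile)
        pm = profile.probe_map
        assert pm.index_of(call.left_flank_probe) == 9
        assert pm.index_of(call.right_flank_probe) == 15

    def test_shoulder_skipped_until_consistent(self):
        # outward from the right breakpoint: -1.1, -0.6, 0.1, 0.0, ...
        profile = self._deletion_profile([-1.1, -0.6, 0.1, 0.0])
        call = self._one_call(profile)
        pm = profile.probe_map
        # -1.1 fails > -0.8; -0.6 passes with 2 of next 3 passing
        assert pm.index_of(call.right_flank_probe) == 16

    def test_amplification_flank_threshold(self):
        x = np.zeros(30)
        x[10:15] = 1.6
        x[15], x[16] = 0.7, 0.1  # 0.7 fails < 0.5, 0.1 passes
        profile = make_profile(x)
        call = self._one_call(profile)
        assert profile.probe_map.index_of(call.right_flank_probe) == 16

    def test_absent_at_chromosome_end(self):
        x = np.zeros(12)
        x[0:4] = -3.0
        profile = make_profile(x)
        call = self._one_call(profile)
        assert call.left_flank_probe is None
        assert profile.probe_map.index_of(call.right_flank_probe) == 4


class TestCallIndels:
    def test_length_is_midpoint_to_midpoint(self):
        starts = [200, 400, 600, 800, 1000, 2000, 3400, 4600, 4800, 5000]
        pm = ProbeMap(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(1, 11)],
            "chromosome": "c1",
            "start": starts,
            "end": [s + 50 for s in starts],
            "region": "center",
        }))
        x = np.zeros(10)
        x[4:7] = -3.0  # probes p5 [1000,1050] .. p7 [3400,3450]
        profile = RatioProfile("t", pm, x, normalized=True)
        call = call_indels(profile)[0]
        assert call.left_bp_probe == "p5" and call.right_bp_probe == "p7"
        assert call.length_bp == 2400  # midpoints 1025 and 3425
        assert (call.start, call.end) == (1000, 3450)

    def test_noise_free_planted_deletion_exact(self):
        x = np.zeros(20)
        x[8:13] = -3.0
        profile = make_profile(x)
        calls = call_indels(profile)
        assert len(calls) == 1
        call = calls[0]
        pm = profile.probe_map
        assert (pm.index_of(call.left_bp_probe), pm.index_of(call.right_bp_probe)) == (8, 12)
        assert call.kind == DELETION and call.n_probes == 5

    def test_sub_cutoff_signal_not_called(self):
        x = np.zeros(30)
        x[10:15] = -1.5  # beyond flank threshold but above deletion cutoff
        profile = make_profile(x)
        assert call_indels(profile) == []

    def test_segmentation_oracle_agreement_rate(self):
        # spot check of the acceptance-scale experiment at smaller n
        rng = np.random.default_rng(17)
        agree = 0
        trials = 40
        for _ in range(trials):
            n = 30
            lo = int(rng.integers(5, 20))
            width = int(rng.integers(3, 9))
            x = rng.normal(0, 0.2, n)
            x[lo : lo + width] += -3.0
            profile = make_profile(x)
            pm = profile.probe_map
            calls = call_indels(profile)
            if calls:
                call = calls[0]
                bounds = (pm.index_of(call.left_bp_probe), pm.index_of(call.right_bp_probe))
                if bounds == least_squares_three_segments(x):
                    agree += 1
        assert agree / trials >= 0.9
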