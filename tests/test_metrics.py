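import numpy as np
import pytest

from microflow import metrics as M
from microflow.model import FlowScore, MetricSet, QualityFlags

import oracles
from conftest import FIVE_VESSEL_EXPECTED, make_clip, make_vessel


class TestClassification:
    @pytest.mark.parametrize("d,expected", [
        (19.9, M.SizeClass.SMALL),
        (20.0, M.SizeClass.MEDIUM),
        (50.0, M.SizeClass.MEDIUM),
        (50.1, M.SizeClass.LARGE),
        (5.0, M.SizeClass.SMALL),
    ])
    def test_size_boundaries(self, d, expected):
        assert M.classify_vessel_size(d) is expected

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            M.classify_vessel_size(0.0)

    @pytest.mark.parametrize("flow,expected", [
        (0, False), (1, False), (2, True), (3, True),
    ])
    def test_perfusion_threshold(self, flow, expected):
        assert M.is_perfused(FlowScore(flow)) is expected


class TestDensities:
    def test_single_spanning_vessel_unit_density(self):
        clip = make_clip([make_vessel("v", [(0, 500), (1000, 500)], 10.0, 3)])
        assert M.compute_tvd(clip) == pytest.approx(1.0)
        assert M.compute_ppv(clip) == pytest.approx(1.0)
        assert M.compute_pvd(clip) == pytest.approx(M.compute_tvd(clip))

    def test_medium_vessel_contributes_nothing(self):
        clip = make_clip([make_vessel("v", [(0, 500), (1000, 500)], 30.0, 3)])
        assert M.compute_tvd(clip) == 0.0
        assert M.compute_ppv(clip) is None
        assert M.compute_pvd(clip) == 0.0
        assert M.compute_de_backer(clip) == 0.0

    def test_ppv_half_for_equal_lengths(self):
        clip = make_clip([
            make_vessel("a", [(0, 100), (1000, 100)], 10.0, 3),
            make_vessel("b", [(0, 900), (1000, 900)], 10.0, 1),
        ])
        assert M.compute_ppv(clip) == pytest.approx(0.5)
        assert M.compute_pvd(clip) == pytest.approx(
            0.5 * M.compute_tvd(clip), rel=1e-12)

    def test_empty_clip_degenerate_contract(self):
        clip = make_clip([])
        ms = M.score_clip(clip)
        assert ms.tvd_mm_per_mm2 == 0.0
        assert ms.pvd_mm_per_mm2 == 0.0
        assert ms.de_backer_n_per_mm == 0.0
        assert ms.ppv_fraction is None
        assert ms.mfi is None
        assert ms.heterogeneity_index is None

    def test_de_backer_spanning_horizontal_vessel(self):
        clip = make_clip([make_vessel("v", [(0, 100), (1000, 100)], 10.0, 3)])
        assert M.compute_de_backer(clip) == pytest.approx(3 / 6.0)

    def test_tvd_against_exact_oracle_on_random_vessels(self, square_fov):
        rng = np.random.default_rng(5)
        rect = (0.0, 0.0, 1000.0, 1000.0)
        vessels = []
        for i in range(50):
            pts = rng.uniform(-300, 1300, size=(int(rng.integers(2, 8)), 2))
            vessels.append(make_vessel(f"v{i}", pts, 10.0, 3))
        clip = make_clip(vessels)
        expected = sum(
            oracles.exact_clipped_length(v.centerline, rect) for v in vessels
        ) / 1000.0 / 1.0
        assert M.compute_tvd(clip) == pytest.approx(expected, rel=1e-9)


class TestQuadrantFlow:
    def test_mode_weighted_by_length(self):
        # TL quadrant: 400 um of flow 3 vs 200 um of flow 1
        clip = make_clip([
            make_vessel("a", [(0, 100), (400, 100)], 10.0, 3),
            make_vessel("b", [(0, 200), (200, 200)], 10.0, 1),
        ])
        q = M.summarize_quadrants(clip)
        assert q[0].mode_score == FlowScore.BRISK
        assert q[1].mode_score is None

    def test_tie_breaks_to_lower_score(self):
        clip = make_clip([
            make_vessel("a", [(0, 100), (300, 100)], 10.0, 2),
            make_vessel("b", [(0, 200), (300, 200)], 10.0, 3),
        ])
        q = M.summarize_quadrants(clip)
        assert q[0].mode_score == FlowScore.MODERATE
        q_hi = M.summarize_quadrants(clip, tie_break="higher")
        assert q_hi[0].mode_score == FlowScore.BRISK

    def test_mfi_mean_of_present_quadrants(self):
        # TL mode 3, TR mode 2, bottom half empty
        clip = make_clip([
            make_vessel("a", [(0, 100), (400, 100)], 10.0, 3),
            make_vessel("b", [(600, 100), (1000, 100)], 10.0, 2),
        ])
        assert M.compute_mfi(clip) == pytest.approx(2.5)
        # zero-convention pulls empty quadrants into the average
        assert M.compute_mfi(clip, empty_quadrant="zero") == pytest.approx(1.25)

    def test_heterogeneity_zero_when_uniform(self):
        clip = make_clip([
            make_vessel(f"v{i}", [(0, y), (1000, y)], 10.0, 3)
            for i, y in enumerate((100, 900))
        ])
        assert M.compute_heterogeneity(clip) == 0.0

    def test_heterogeneity_all_absent_flow_is_zero(self):
        clip = make_clip([
            make_vessel(f"v{i}", [(0, y), (1000, y)], 10.0, 0)
            for i, y in enumerate((100, 900))
        ])
        assert M.compute_heterogeneity(clip) == 0.0

    def test_heterogeneity_needs_two_quadrants(self):
        clip = make_clip([make_vessel("a", [(0, 100), (400, 100)], 10.0, 3)])
        assert M.compute_heterogeneity(clip) is None


class TestFiveVesselFixture:
    def test_matches_hand_computation(self, five_vessel_clip):
        ms = M.score_clip(five_vessel_clip)
        for key, expected in FIVE_VESSEL_EXPECTED.items():
            assert getattr(ms, key) == pytest.approx(expected, rel=1e-9), key

    def test_quadrant_modes(self, five_vessel_clip):
        modes = [q.mode_score for q in M.summarize_quadrants(five_vessel_clip)]
        assert [int(m) for m in modes] == [2, 3, 1, 2]


class TestInvariantProperties:
    def _random_clip_small_only(self, rng):
        vessels = [
            make_vessel(
                f"v{i}",
                rng.uniform(-200, 1200, size=(int(rng.integers(2, 6)), 2)),
                float(rng.uniform(5, 19)),
                int(rng.integers(0, 4)),
            )
            for i in range(int(rng.integers(1, 6)))
        ]
        return make_clip(vessels)

    def test_bounds_and_product_identity(self):
        rng = np.random.default_rng(31)
        for _ in range(40):
            clip = self._random_clip_small_only(rng)
            ms = M.score_clip(clip)
            assert 0.0 <= ms.pvd_mm_per_mm2 <= ms.tvd_mm_per_mm2 + 1e-12
            if ms.ppv_fraction is not None:
                assert 0.0 <= ms.ppv_fraction <= 1.0
                assert ms.pvd_mm_per_mm2 == pytest.approx(
                    ms.ppv_fraction * ms.tvd_mm_per_mm2, abs=1e-12)
            if ms.mfi is not None:
                assert 0.0 <= ms.mfi <= 3.0
            if ms.heterogeneity_index is not None:
                assert ms.heterogeneity_index >= 0.0

    def test_adding_perfused_vessel_monotone(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            clip = self._random_clip_small_only(rng)
            extra = make_vessel(
                "extra", rng.uniform(0, 1000, size=(4, 2)), 10.0, 3)
            bigger = make_clip(list(clip.vessels) + [extra])
            assert M.compute_tvd(bigger) >= M.compute_tvd(clip) - 1e-12
            assert M.compute_pvd(bigger) >= M.compute_pvd(clip) - 1e-12
            assert M.compute_de_backer(bigger) >= M.compute_de_backer(clip)

    def test_adding_unperfused_vessel_never_raises_ppv(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            clip = self._random_clip_small_only(rng)
            ppv0 = M.compute_ppv(clip)
            extra = make_vessel(
                "extra", rng.uniform(0, 1000, size=(4, 2)), 10.0, 1)
            ppv1 = M.compute_ppv(make_clip(list(clip.vessels) + [extra]))
            if ppv0 is not None:
                assert ppv1 <= ppv0 + 1e-12

    def test_doubling_lengths_doubles_densities(self):
        # two parallel spanning vessels vs one: same FOV, doubled length
        one = make_clip([make_vessel("a", [(0, 100), (1000, 100)], 10.0, 3)])
        two = make_clip([
            make_vessel("a", [(0, 100), (1000, 100)], 10.0, 3),
            make_vessel("b", [(0, 200), (1000, 200)], 10.0, 3),
        ])
        assert M.compute_tvd(two) == pytest.approx(2 * M.compute_tvd(one))
        assert M.compute_pvd(two) == pytest.approx(2 * M.compute_pvd(one))
        assert M.compute_ppv(two) == pytest.approx(M.compute_ppv(one))


class TestClipSelection:
    def _clip(self, cid, duration=5.0, **flags):
        return make_clip([], clip_id=cid, duration=duration,
                         quality=QualityFlags(**flags))

    def test_top_three_of_five_clean_clips(self):
        clips = [self._clip(f"c{i}", duration=4 + i) for i in range(5)]
        chosen = M.rank_and_select_clips(clips)
        assert len(chosen) == 3
        # ties on quality resolve to the longest durations
        assert [c.clip_id for c in chosen] == ["c4", "c3", "c2"]

    def test_pressure_artifact_never_selected(self):
        clips = [self._clip("bad", pressure_artifact=True), self._clip("ok")]
        chosen = M.rank_and_select_clips(clips)
        assert [c.clip_id for c in chosen] == ["ok"]

    def test_duration_window_enforced(self):
        clips = [self._clip("short", duration=2.0),
                 self._clip("long", duration=12.0),
                 self._clip("ok", duration=3.0)]
        assert [c.clip_id for c in M.rank_and_select_clips(clips)] == ["ok"]

    def test_fewer_than_max_returned_as_is(self):
        clips = [self._clip("a"), self._clip("b")]
        assert len(M.rank_and_select_clips(clips)) == 2

    def test_quality_ranking_beats_duration(self):
        good = self._clip("good", duration=4.0)
        blurry = self._clip("blurry", duration=9.0, out_of_focus=True)
        assert [c.clip_id for c in M.rank_and_select_clips([blurry, good],
                                                           max_n=1)] == ["good"]

    def test_mixed_subjects_rejected(self):
        a = make_clip([], clip_id="a", subject_id="S1")
        b = make_clip([], clip_id="b", subject_id="S2")
        with pytest.raises(ValueError):
            M.rank_and_select_clips([a, b])


class TestAggregation:
    def test_single_clip_identity(self, five_vessel_clip):
        ms = M.score_clip(five_vessel_clip)
        assert M.aggregate_time_point([ms]) == ms

    def test_mean_of_densities(self):
        a = MetricSet(20.0, 18.0, 0.9, 3.0, 0.0, 13.0)
        b = MetricSet(24.0, 20.0, 0.8, 2.0, 0.5, 15.0)
        agg = M.aggregate_time_point([a, b])
        assert agg.tvd_mm_per_mm2 == pytest.approx(22.0)
        assert agg.de_backer_n_per_mm == pytest.approx(14.0)

    def test_missing_values_skipped_not_zeroed(self):
        a = MetricSet(20.0, 18.0, 0.9, 3.0, None, 13.0)
        b = MetricSet(24.0, 20.0, None, None, None, 15.0)
        c = MetricSet(22.0, 19.0, 0.8, 2.0, None, 14.0)
        agg = M.aggregate_time_point([a, b, c])
        assert agg.mfi == pytest.approx(2.5)
        assert agg.ppv_fraction == pytest.approx(0.85)
        assert agg.heterogeneity_index is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            M.aggregate_time_point([])
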