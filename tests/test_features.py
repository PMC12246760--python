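"""Cleaning, per-swipe kinematics, IQR filtering, catalog and aggregation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swipescreen.features import (
    CatalogError,
    CleaningConfig,
    PRESS_WINDOW,
    TapError,
    aggregate_session,
    build_catalog,
    clean_swipes,
    derive_swipe_metrics,
    feature_table,
    iqr_filter,
    quantize_direction,
)
from swipescreen.model import GameSession


def _path(points):
    return np.asarray(points, dtype=float)


class TestDeriveSwipeMetrics:
    def test_straight_path_pythagoras(self):
        p = _path([[0.0, 0.0, 0.0, 0.4], [0.5, 3.0, 4.0, 0.4]])
        swp = derive_swipe_metrics(p, swipe_id=1, event_time=1.0, start_time=0.5,
                                   game="puzzle")
        assert swp.distance == pytest.approx(5.0)
        assert swp.speed == pytest.approx(10.0)
        assert swp.duration == pytest.approx(0.5)
        assert swp.end_time == pytest.approx(1.0)

    def test_segment_sum(self):
        p = _path([[0.0, 0.0, 0.0, 0.3], [0.5, 3.0, 0.0, 0.3], [1.0, 3.0, 4.0, 0.3]])
        swp = derive_swipe_metrics(p, swipe_id=1, event_time=0.0, start_time=0.0,
                                   game="slicer")
        assert swp.distance == pytest.approx(7.0)
        assert swp.speed == pytest.approx(7.0)
        assert swp.direction == "none"

    def test_constant_pressure(self):
        p = _path([[t / 10, 10 * t, 5.0, 0.4] for t in range(8)])
        swp = derive_swipe_metrics(p, swipe_id=1, event_time=0.0, start_time=0.0,
                                   game="puzzle")
        assert swp.press_mean == pytest.approx(0.4)
        assert swp.press_variance == pytest.approx(0.0)
        assert swp.start_press_variance == pytest.approx(0.0)
        assert swp.end_press_variance == pytest.approx(0.0)

    def test_press_windows_use_k_points(self):
        press = [0.1, 0.2, 0.3, 0.4, 0.5, 0.9, 0.9, 0.9, 0.9, 0.9]
        p = _path([[i * 0.1, i * 20.0, 0.0, pr] for i, pr in enumerate(press)])
        swp = derive_swipe_metrics(p, swipe_id=1, event_time=0.0, start_time=0.0,
                                   game="puzzle")
        assert swp.start_press_variance == pytest.approx(
            np.var(press[:PRESS_WINDOW], ddof=1))
        assert swp.end_press_variance == pytest.approx(
            np.var(press[-PRESS_WINDOW:], ddof=1))

    def test_displacement_speed_mode(self):
        p = _path([[0.0, 0.0, 0.0, 0.3], [0.5, 3.0, 0.0, 0.3], [1.0, 3.0, 4.0, 0.3]])
        cfg = CleaningConfig(speed_mode="displacement")
        swp = derive_swipe_metrics(p, swipe_id=1, event_time=0.0, start_time=0.0,
                                   game="slicer", config=cfg)
        assert swp.speed == pytest.approx(5.0)  # net displacement over duration
        assert swp.distance == pytest.approx(7.0)  # distance stays path length

    @pytest.mark.parametrize("path", [
        [[0.0, 1.0, 1.0, 0.2]],                       # single point
        [[0.0, 0.0, 0.0, 0.2], [0.0, 5.0, 5.0, 0.2]],  # zero duration
    ])
    def test_tap_rejection(self, path):
        with pytest.raises(TapError):
            derive_swipe_metrics(_path(path), swipe_id=1, event_time=0.0,
                                 start_time=0.0, game="puzzle")

    def test_recomputation_matches_generated_logs(self, tiny_cohort):
        """Writer/deriver self-consistency: re-deriving from the stored path
        reproduces every stored per-swipe metric."""
        sessions, _ = tiny_cohort
        for session in sessions[:3]:
            for swp in session.swipes[:10]:
                re = derive_swipe_metrics(
                    swp.path, swipe_id=swp.swipe_id, event_time=swp.event_time,
                    start_time=swp.start_time, game=session.game,
                    time_between_swipes=swp.time_between_swipes)
                for attr in ("speed", "duration", "distance", "press_mean",
                             "press_variance", "start_press", "end_press",
                             "start_press_variance", "end_press_variance"):
                    assert getattr(re, attr) == pytest.approx(
                        getattr(swp, attr), abs=1e-6), attr
                assert re.direction == swp.direction


class TestQuantizeDirection:
    @pytest.mark.parametrize("dx, dy, expected", [
        (10, 2, "right"),
        (0, -8, "down"),
        (5, 5, "right"),     # tie goes horizontal
        (-5, 5, "left"),
        (-2, 30, "up"),
        (-7, -6, "left"),
    ])
    def test_dominant_axis(self, dx, dy, expected):
        assert quantize_direction(dx, dy) == expected

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            quantize_direction(0, 0)


class TestIqrFilter:
    def test_single_outlier_removed(self):
        # hand-checked fences: Q1=3.25, Q3=7.75, IQR=4.5 -> [-3.5, 14.5]
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9, 100]
        kept, mask = iqr_filter(values, 1.5)
        assert kept.tolist() == values[:-1]
        assert mask.tolist() == [False] * 9 + [True]

    def test_constant_sequence_untouched(self):
        kept, mask = iqr_filter([5.0] * 10)
        assert kept.tolist() == [5.0] * 10
        assert not mask.any()

    def test_small_n_passthrough(self):
        kept, mask = iqr_filter([1.0, 50.0, -70.0])
        assert kept.tolist() == [1.0, 50.0, -70.0]
        assert not mask.any()

    @given(st.lists(st.floats(-1e6, 1e6), min_size=0, max_size=60),
           st.floats(0.5, 3.0))
    def test_output_is_subsequence_and_deterministic(self, values, m):
        kept1, mask1 = iqr_filter(values, m)
        kept2, mask2 = iqr_filter(values, m)
        assert kept1.tolist() == kept2.tolist()
        assert mask1.tolist() == mask2.tolist()
        assert kept1.tolist() == [v for v, bad in zip(values, mask1) if not bad]


class TestCleanSwipes:
    def test_menu_swipes_removed(self, tiny_cohort):
        sessions, _ = tiny_cohort
        session = sessions[0]
        # push two swipes outside the gameplay window
        moved = dataclasses.replace(session)
        moved.swipes = list(session.swipes)
        for k in range(2):
            moved.swipes[k] = dataclasses.replace(moved.swipes[k], event_time=1.0)
        moved.swipes.sort(key=lambda s: s.event_time)
        cleaned, log = clean_swipes(moved, CleaningConfig())
        assert log["menu"] == 2
        assert len(cleaned.swipes) == len(session.swipes) - 2

    def test_sub_threshold_tap_removed(self):
        from tests.test_model_io import _manual_session
        session = _manual_session()
        tap = derive_swipe_metrics(
            _path([[0.0, 50.0, 50.0, 0.3], [0.1, 51.0, 50.0, 0.3]]),
            swipe_id=3, event_time=30.0, start_time=20.0, game="puzzle")
        session.swipes.append(tap)
        cleaned, log = clean_swipes(session, CleaningConfig(min_swipe_distance=20))
        assert log == {"menu": 0, "sub_threshold": 1}
        assert [s.swipe_id for s in cleaned.swipes] == [1, 2]

    def test_identity_when_all_valid(self, tiny_cohort):
        sessions, _ = tiny_cohort
        cleaned, log = clean_swipes(sessions[0], CleaningConfig())
        assert log == {"menu": 0, "sub_threshold": 0}
        assert cleaned.swipes == sessions[0].swipes
        assert cleaned is not sessions[0]


class TestCatalog:
    @pytest.mark.parametrize("game, lo, hi", [("puzzle", 140, 160),
                                              ("runner", 140, 160),
                                              ("slicer", 140, 160)])
    def test_size_band(self, game, lo, hi):
        assert lo <= len(build_catalog(game)) <= hi

    def test_expected_members(self):
        puzzle = build_catalog("puzzle").names
        assert "swipe_press_variance_std" in puzzle
        assert "swipe_speed_mean" in puzzle
        assert "acl_X_std" in puzzle and "gyro_Y_range" in puzzle
        assert "time_between_swipes_std" in puzzle
        runner = build_catalog("runner").names
        assert "swipe_count" in runner and "swipe_count_up" in runner
        slicer = build_catalog("slicer").names
        assert not any("count_" in n or "direction" in n for n in slicer)
        assert "swipe_start_posY_min" in slicer and "swipe_posY_std" in slicer

    def test_names_unique_and_composed(self):
        for game in ("puzzle", "runner", "slicer"):
            cat = build_catalog(game)
            assert len(set(cat.names)) == len(cat)
            for e in cat.entries:
                assert e.name == f"{e.base}_{e.aggregator}" or e.base == "swipe_count"

    def test_unknown_game(self):
        with pytest.raises(CatalogError):
            build_catalog("racing")


class TestAggregation:
    def _session_with_speeds(self, speeds):
        from tests.test_model_io import _manual_session
        session = _manual_session()
        swipes = []
        for i, v in enumerate(speeds):
            dur = 0.5
            p = _path([[0.0, 100.0, 100.0, 0.4],
                       [dur, 100.0 + v * dur, 100.0, 0.4]])
            swipes.append(derive_swipe_metrics(
                p, swipe_id=i + 1, event_time=10.0 + 2.0 * i, start_time=0.0,
                game="puzzle", time_between_swipes=None if i == 0 else 1.5))
        session.swipes = swipes
        return session

    def test_eight_aggregators_on_speeds(self):
        fv = aggregate_session(self._session_with_speeds([2.0, 4.0, 6.0]))
        v = fv.values
        assert v["swipe_speed_mean"] == pytest.approx(4.0)
        assert v["swipe_speed_median"] == pytest.approx(4.0)
        assert v["swipe_speed_min"] == pytest.approx(2.0)
        assert v["swipe_speed_max"] == pytest.approx(6.0)
        assert v["swipe_speed_range"] == pytest.approx(4.0)
        assert v["swipe_speed_first"] == pytest.approx(2.0)
        assert v["swipe_speed_last"] == pytest.approx(6.0)
        assert v["swipe_speed_std"] == pytest.approx(2.0)  # sample SD

    def test_zero_swipes(self):
        session = self._session_with_speeds([])
        fv = aggregate_session(session)
        assert fv.values["swipe_count"] == 0
        assert np.isnan(fv.values["swipe_speed_mean"])
        assert np.isnan(fv.values["swipe_press_variance_std"])
        # sensor features still defined
        assert np.isfinite(fv.values["acl_X_mean"])

    def test_constant_sensor_axis(self):
        import swipescreen as swp
        session = self._session_with_speeds([2.0, 4.0])
        session.sensors = {"accelerometer": swp.SensorStream(
            "accelerometer", np.arange(5) / 2.0,
            np.column_stack([np.full(5, 0.1), np.zeros(5), np.ones(5)]))}
        fv = aggregate_session(session)
        assert fv.values["acl_X_std"] == pytest.approx(0.0)
        assert fv.values["acl_X_range"] == pytest.approx(0.0)
        assert fv.values["acl_X_mean"] == pytest.approx(0.1)
        assert np.isnan(fv.values["gyro_X_mean"])  # stream absent -> missing

    def test_catalog_game_mismatch(self):
        session = self._session_with_speeds([2.0])
        with pytest.raises(CatalogError):
            aggregate_session(session, build_catalog("slicer"))

    def test_aggregation_identities(self, tiny_cohort):
        """min <= median <= max, range = max - min, first/last are members,
        SD >= 0 — across every base of a generated session."""
        sessions, _ = tiny_cohort
        session, _ = clean_swipes(sessions[0], CleaningConfig())
        fv = aggregate_session(session)
        v = fv.values
        bases = sorted({e.base for e in build_catalog(session.game).entries
                        if f"{e.base}_median" in v})
        assert bases
        for base in bases:
            if not np.isfinite(v.get(f"{base}_median", np.nan)):
                continue
            assert v[f"{base}_min"] <= v[f"{base}_median"] <= v[f"{base}_max"]
            if f"{base}_range" in v:
                assert v[f"{base}_range"] == pytest.approx(
                    v[f"{base}_max"] - v[f"{base}_min"])
            if f"{base}_std" in v and np.isfinite(v[f"{base}_std"]):
                assert v[f"{base}_std"] >= 0
            if f"{base}_first" in v:
                assert v[f"{base}_min"] - 1e-9 <= v[f"{base}_first"] <= v[f"{base}_max"] + 1e-9
                assert v[f"{base}_min"] - 1e-9 <= v[f"{base}_last"] <= v[f"{base}_max"] + 1e-9

    def test_extraction_is_permutation_safe(self, rng):
        session = self._session_with_speeds([3.0, 7.0, 5.0, 9.0, 2.0])
        fv1 = aggregate_session(session)
        shuffled = dataclasses.replace(session)
        shuffled.swipes = list(session.swipes)
        rng.shuffle(shuffled.swipes)
        fv2 = aggregate_session(shuffled)
        for k in fv1.values:
            a, b = fv1.values[k], fv2.values[k]
            assert (a == b) or (np.isnan(a) and np.isnan(b)), k


def test_feature_table_shape_and_pooled_mode(tiny_cohort):
    sessions, _ = tiny_cohort
    puzzle = [s for s in sessions if s.game == "puzzle"]
    df = feature_table(puzzle)
    assert df.shape == (5, len(build_catalog("puzzle")))
    assert df.index.name == "participant_id"
    pooled = feature_table(puzzle, CleaningConfig(iqr_scope="pooled_metric"))
    assert pooled.shape == df.shape
    # pooled filtering may only introduce missingness, never alter counts
    assert (pooled["swipe_count"] == df["swipe_count"]).all()
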