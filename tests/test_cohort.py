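"""Synthetic cohort generator: determinism, validity, calibration machinery."""

import dataclasses
import math

import numpy as np
import pytest

import swipescreen as sw
from swipescreen.cohort import (
    ATTENUATION,
    CalibrationError,
    CohortConfig,
    CohortConfigError,
    DEFAULT_EFFECTS,
    EffectSpec,
    _solve_loadings,
    build_profile,
    calibrate_effect,
    generate_cohort,
    generate_item_responses,
    item_model,
    resolve_effects,
)
from swipescreen.features import CleaningConfig, feature_table
from swipescreen.io import link_records
from swipescreen.questionnaires import score_table
from swipescreen.screen import correlate_features
from tests.conftest import tiny_config


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_participants=0),
        dict(gad7_sd=-1.0),
        dict(trait_correlation=1.5),
        dict(games=("puzzle", "chess")),
        dict(n_participants=5, unmatched_id_count=6),
        dict(gameplay_window=(100.0, 50.0)),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(CohortConfigError):
            CohortConfig(**kwargs)

    def test_effect_spec_must_be_in_catalog(self):
        with pytest.raises(CohortConfigError):
            EffectSpec("slicer", "swipe_count_up", "GAD7", 0.3, mechanism="speed")
        with pytest.raises(CohortConfigError):
            EffectSpec("puzzle", "swipe_speed_mean", "GAD7", 1.2)


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = tiny_config(seed=7)
        s1, q1 = generate_cohort(cfg)
        s2, q2 = generate_cohort(cfg)
        assert q1.equals(q2)
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            assert sw.sessions_equal(a, b, tol=0.0)

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = tiny_config(seed=8, games=("puzzle",), n_participants=2)
        for run in ("a", "b"):
            sessions, _ = generate_cohort(cfg)
            sw.write_session_log(sessions[0], tmp_path / f"{run}.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_different_seed_differs(self):
        s1, q1 = generate_cohort(tiny_config(seed=1))
        s2, q2 = generate_cohort(tiny_config(seed=2))
        assert not q1.equals(q2)


class TestSessions:
    def test_generated_sessions_always_validate(self, tiny_cohort):
        sessions, _ = tiny_cohort
        for session in sessions:
            assert sw.validate_session(session) == []

    def test_bounds_and_session_limit(self, tiny_cohort):
        sessions, _ = tiny_cohort
        for s in sessions:
            w, h = s.screen_dims
            for swp in s.swipes:
                assert swp.event_time <= s.session_limit
                assert swp.path[:, 1].min() >= 0 and swp.path[:, 1].max() <= w
                assert swp.path[:, 2].min() >= 0 and swp.path[:, 2].max() <= h
                assert 0 <= swp.path[:, 3].min() and swp.path[:, 3].max() <= 1

    def test_runner_portrait_with_four_directions(self, tiny_cohort):
        sessions, _ = tiny_cohort
        runners = [s for s in sessions if s.game == "runner"]
        assert runners
        for s in runners:
            assert s.orientation == "portrait"
            assert s.screen_dims == (1080, 2400)
            assert {swp.direction for swp in s.swipes} <= {"up", "down", "left", "right"}

    def test_slicer_direction_none_and_longer_swipes(self, tiny_cohort):
        sessions, _ = tiny_cohort
        slicers = [s for s in sessions if s.game == "slicer"]
        puzzles = [s for s in sessions if s.game == "puzzle"]
        assert all(swp.direction == "none" for s in slicers for swp in s.swipes)
        mean_len = lambda ss: np.mean([swp.distance for s in ss for swp in s.swipes])
        assert mean_len(slicers) > mean_len(puzzles)

    def test_sensor_streams_cover_session(self, tiny_cohort):
        sessions, _ = tiny_cohort
        s = sessions[0]
        for stream in s.sensors.values():
            assert len(stream) == int(s.session_limit * 2.0)  # tiny config: 2 Hz
            assert stream.t[-1] <= s.session_limit


class TestItemResponses:
    def test_extreme_negative_latent_floors_items(self, rng):
        items = generate_item_responses(-50.0, "GAD7", CohortConfig(), rng)
        assert items.tolist() == [0] * 7

    def test_extreme_positive_latent_caps_items(self, rng):
        items = generate_item_responses(50.0, "PHQ8", CohortConfig(), rng)
        assert items.tolist() == [3] * 8

    def test_items_always_in_range(self, rng):
        for z in rng.normal(size=200):
            items = generate_item_responses(z, "GAD7", CohortConfig(), rng)
            assert items.min() >= 0 and items.max() <= 3 and len(items) == 7

    def test_population_means_match_targets(self, rng):
        """Single large sample: totals hit the configured mean within 0.3."""
        cfg = CohortConfig()
        z = rng.normal(size=4000)
        gad = np.array([generate_item_responses(v, "GAD7", cfg, rng).sum() for v in z[:2000]])
        phq = np.array([generate_item_responses(v, "PHQ8", cfg, rng).sum() for v in z[2000:]])
        assert gad.mean() == pytest.approx(9.09, abs=0.3)
        assert phq.mean() == pytest.approx(8.24, abs=0.3)
        assert gad.std(ddof=1) == pytest.approx(5.26, abs=0.5)

    def test_item_model_moments_are_solved_exactly(self):
        im = item_model(7, 9.09, 5.26, 0.9)
        assert im.mean_total == pytest.approx(9.09, abs=1e-6)
        assert im.sd_total == pytest.approx(5.26, abs=1e-6)
        assert 0 < im.r_latent < 1


class TestLinkageScenario:
    def test_unmatched_ids_yield_smaller_linked_cohort(self):
        cfg = tiny_config(n_participants=8, unmatched_id_count=2, games=("puzzle",))
        sessions, questionnaires = generate_cohort(cfg)
        records, drop_log = link_records(sessions, questionnaires)
        assert len(records) == 6
        reasons = {r for _, r in drop_log}
        assert reasons == {"no_questionnaire", "no_sessions"}


class TestLoadingSolver:
    def test_zero_target_gives_zero_loadings(self):
        eff = _solve_loadings({"PHQ8": 0.0}, CohortConfig(), "puzzle", "speed")
        assert eff.w_dep == 0.0 and eff.w_anx == 0.0 and eff.w_noise == 1.0

    def test_loadings_monotone_in_target(self):
        cfg = CohortConfig()
        sizes = []
        for target in (0.1, 0.2, 0.3, 0.4):
            eff = _solve_loadings({"PHQ8": target}, cfg, "puzzle", "speed", 0.95)
            sizes.append(abs(eff.w_dep))
            assert eff.w_anx == 0.0
        assert sizes == sorted(sizes)

    def test_sign_follows_target(self):
        eff = _solve_loadings({"GAD7": -0.4}, CohortConfig(), "puzzle", "speed", 0.95)
        assert eff.w_anx < 0 and eff.w_dep == 0.0

    def test_unit_variance_decomposition(self):
        cfg = CohortConfig()
        for key, eff in resolve_effects(cfg).items():
            rho = cfg.trait_correlation
            var = (eff.w_dep ** 2 + eff.w_anx ** 2
                   + 2 * rho * eff.w_dep * eff.w_anx + eff.w_noise ** 2)
            assert var == pytest.approx(1.0, abs=1e-9)

    def test_unattainable_target_raises(self):
        with pytest.raises(CalibrationError):
            _solve_loadings({"PHQ8": 0.95}, CohortConfig(), "puzzle", "speed", 0.5)

    def test_effects_never_change_marginals(self, rng):
        """Planted effects alter only correlations: a strongly-planted profile
        parameter keeps the same marginal spread as a null one."""
        cfg_null = CohortConfig(effects=())
        cfg_eff = CohortConfig()
        effects_null = resolve_effects(cfg_null)
        effects_eff = resolve_effects(cfg_eff)
        vals = {"null": [], "eff": []}
        for i in range(400):
            z = rng.normal(size=2)
            p_null = build_profile("x", z[0], z[1], cfg_null, effects_null,
                                   np.random.default_rng(1000 + i))
            p_eff = build_profile("x", z[0], z[1], cfg_eff, effects_eff,
                                  np.random.default_rng(1000 + i))
            vals["null"].append(math.log(p_null.params["puzzle"]["speed"]))
            vals["eff"].append(math.log(p_eff.params["puzzle"]["speed"]))
        sd_null = np.std(vals["null"], ddof=1)
        sd_eff = np.std(vals["eff"], ddof=1)
        assert sd_eff == pytest.approx(sd_null, rel=0.15)


class TestNullCalibration:
    def test_null_pipeline_type_one_rate(self):
        """With an empty effect map the full pipeline's per-feature P<.05 rate
        sits near 0.05. Band [0.02, 0.08] allows for the strong dependence
        between aggregators of one base metric (effective sample size is far
        below the nominal number of tests). Sessions are scaled down for
        runtime; the statistics under test do not depend on session length.
        """
        reps, hits, total = 12, 0, 0
        for rep in range(reps):
            cfg = tiny_config(
                n_participants=40, seed=500 + rep, effects=(),
                games=("puzzle",),
                swipes_per_session={"puzzle": 60, "runner": 60, "slicer": 60},
                sensor_rate_hz=4.0)
            sessions, questionnaires = generate_cohort(cfg)
            scored = score_table(questionnaires)
            totals = {
                inst: scored.set_index("participant_id")[f"{inst.lower()}_total"]
                for inst in ("GAD7", "PHQ8")
            }
            feats = feature_table(sessions)
            results = correlate_features(feats, totals)
            hits += sum(r.p_value < 0.05 for r in results)
            total += len(results)
        assert total > 2000
        assert 0.02 <= hits / total <= 0.08


class TestCalibrateEffect:
    def test_zero_target_short_circuits(self):
        spec = EffectSpec("puzzle", "swipe_speed_mean", "PHQ8", 0.0)
        cfg = CohortConfig(effects=(spec,))
        eff = calibrate_effect(spec, cfg)
        assert eff.w_dep == eff.w_anx == 0.0 and eff.w_noise == 1.0

    def test_monte_carlo_refinement_moves_toward_target(self):
        """Scaled-down end-to-end calibration: the refined attenuation yields a
        mean recovered rho close to the target."""
        spec = EffectSpec("puzzle", "swipe_speed_mean", "PHQ8", -0.35)
        cfg = tiny_config(
            n_participants=60, effects=(spec,), games=("puzzle",),
            swipes_per_session={"puzzle": 50, "runner": 50, "slicer": 50},
            sensor_rate_hz=4.0)
        eff = calibrate_effect(spec, cfg, n_reps=25, n_participants=60,
                               max_iter=3, tol=0.04, seed=3)
        assert eff.achieved is not None
        assert eff.achieved["PHQ8"] == pytest.approx(-0.35, abs=0.06)
        assert eff.w_dep < 0
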