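"""Tests for the synthetic cohort generator."""

import math

import numpy as np
import pytest

import cipredict as cp
from cipredict.exceptions import ValidationError


class TestConfig:
    def test_packaged_default_matches_dataclass(self):
        assert cp.default_generator_config() == cp.GeneratorConfig()

    def test_json_roundtrip(self, tmp_path):
        cfg = cp.GeneratorConfig(n_patients=7, seed=3, ha_attenuation=0.2)
        path = tmp_path / "gen.json"
        cfg.to_json(path)
        assert cp.GeneratorConfig.from_json(path) == cfg

    @pytest.mark.parametrize("kwargs", [
        {"n_patients": -1},
        {"n_items": 0},
        {"age_range": (86.0, 25.0)},
        {"ha_attenuation": 0.0},
        {"pattern_rate_flat": 0.7, "pattern_rate_fluctuating": 0.7},
        {"followup_months": (3.0, 2.0)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            cp.GeneratorConfig(**kwargs)


class TestGenerate:
    def test_empty_cohort(self):
        assert cp.generate_cohort(cp.GeneratorConfig(n_patients=0)) == []

    def test_deterministic_and_seed_sensitive(self):
        a = cp.generate_cohort(cp.GeneratorConfig(n_patients=30, seed=5))
        b = cp.generate_cohort(cp.GeneratorConfig(n_patients=30, seed=5))
        c = cp.generate_cohort(cp.GeneratorConfig(n_patients=30, seed=6))
        assert a == b
        assert a != c

    def test_inclusion_and_attainability(self, small_cohort):
        cfg = cp.GeneratorConfig()
        step = 100.0 / cfg.n_items
        for pt in small_cohort:
            assert pt.profile.wrs65_ha <= 50.0
            assert pt.latent_p_ha <= pt.latent_p_max + 1e-12
            for score in (pt.profile.wrs_max, pt.profile.wrs65_ha,
                          *pt.followup.scores):
                assert math.isclose(score / step, round(score / step), abs_tol=1e-9)
            assert pt.followup.months == cfg.followup_months
            assert pt.injected_pattern in ("none", "flat", "fluctuating")

    def test_fpta_consistent_with_audiogram(self, small_cohort):
        for pt in small_cohort:
            assert pt.profile.fpta_ipsi == cp.four_freq_pta(pt.audiogram)

    def test_trajectories_rise_in_expectation(self, small_cohort):
        """Without injected patterns the latent course is non-decreasing;
        check the mean measured course over clean patients rises."""
        clean = [p for p in small_cohort if p.injected_pattern == "none"]
        scores = np.array([p.followup.scores for p in clean])
        means = scores.mean(axis=0)
        assert means[0] < means[-1]
        assert np.all(np.diff(means) > -3.0)  # binomial jitter only

    def test_noise_free_limit_concentrates_on_prediction(self):
        """With no attenuation, a huge word list, instant rehabilitation
        and no injected patterns, the 6-month score equals the model
        prediction up to vanishing binomial noise."""
        cfg = cp.GeneratorConfig(
            n_patients=50, seed=9, ha_attenuation=1.0, n_items=2000,
            wrsmax_logit_intercept=2.0,  # keep aided scores inside inclusion
            trajectory_tau_log_mean=math.log(0.01), trajectory_tau_log_sd=0.0,
            pattern_rate_flat=0.0, pattern_rate_fluctuating=0.0)
        for pt in cp.generate_cohort(cfg):
            predicted = cp.predict_wrs_ci(cp.DEFAULT_COEFFICIENTS, pt.profile).point
            measured_6mo = pt.followup.score_at(6.0, window=0.5)
            assert abs(measured_6mo - predicted) < 5.0

    def test_unsatisfiable_inclusion_raises(self):
        cfg = cp.GeneratorConfig(
            n_patients=20, seed=1, ha_attenuation=1.0, max_resample=5,
            p_wrsmax_zero_intercept=-100.0,  # nobody scores zero
            wrsmax_logit_intercept=60.0, wrsmax_logit_sd=0.01,  # p_max ~ 1
        )
        with pytest.raises(cp.GenerationError):
            cp.generate_cohort(cfg)


class TestTables:
    def test_row_counts(self, small_cohort):
        preop, followup = cp.cohort_to_tables(small_cohort)
        assert len(preop) == len(small_cohort)
        assert len(followup) == len(small_cohort) * len(small_cohort[0].followup.months)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            cp.cohort_to_tables([])

    def test_roundtrip_through_files(self, tmp_path, small_cohort):
        preop, followup = cp.cohort_to_tables(small_cohort)
        pp, fp = tmp_path / "preop.csv", tmp_path / "followup.csv"
        cp.write_tables(preop, followup, pp, fp)
        records = cp.read_preop_table(pp)
        series, orphans = cp.read_followup_table(fp, records)
        assert orphans == []
        assert len(records) == len(small_cohort)
        for pt in small_cohort:
            rec = records[pt.patient_id]
            assert rec.profile == pt.profile
            assert rec.audiogram == pt.audiogram
            assert series[pt.patient_id] == pt.followup


class TestFollowUpSeries:
    def test_validation(self):
        with pytest.raises(ValidationError):
            cp.FollowUpSeries(months=(3.0, 2.0), scores=(10.0, 20.0))
        with pytest.raises(ValidationError):
            cp.FollowUpSeries(months=(1.0, 2.0), scores=(10.0, 120.0))
        with pytest.raises(ValidationError):
            cp.FollowUpSeries(months=(1.0,), scores=(10.0, 20.0))

    def test_score_at_window(self):
        fu = cp.FollowUpSeries(months=(1.0, 2.0, 5.5, 12.0),
                               scores=(10.0, 20.0, 45.0, 50.0))
        assert fu.score_at(6.0, window=1.0) == 45.0
        assert fu.score_at(6.0, window=0.25) is None
        assert fu.score_at(12.0) == 50.0
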