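"""Synthetic cohort generator: determinism, schedules, burst structure,
and the generative well-being model."""

import numpy as np
import pandas as pd
import pytest

from actiwell import (
    CohortConfig,
    ConfigError,
    GenerativeCoefficients,
    ParticipantProfile,
    extract_features,
    generate_profiles,
    generate_timelines,
    generate_wellbeing,
    synthesize_burst,
)
from actiwell.synthetic import ACTIVE, STILL, _rng_for


def _profiles(cfg, **kw):
    return [
        ParticipantProfile(participant_id=f"p{i:03d}", **kw) for i in range(cfg.n_participants)
    ]


class TestConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_participants=0),
            dict(n_days=0),
            dict(burst_rate_hz=5),
            dict(missingness_prob=1.0),
            dict(survey_windows=((400, 600),)),  # starts before 08:00
            dict(survey_windows=((480, 700), (650, 900))),  # overlap
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            CohortConfig(**bad).validate()

    def test_generative_defaults_match_reported_effects(self):
        mood = GenerativeCoefficients.mood_defaults()
        assert mood.intercept == 5.056
        assert mood.beta_activity == 0.097
        assert mood.beta_sleep == 0.072
        energy = GenerativeCoefficients.energy_defaults()
        assert energy.intercept == 5.686
        assert energy.beta_activity == 0.182


class TestTimelines:
    def test_degenerate_schedule_gives_identical_nights(self):
        cfg = CohortConfig(n_participants=2, n_days=5, missingness_prob=0.0, seed=1)
        profiles = _profiles(cfg, schedule_jitter_sd=0.0)
        tls = generate_timelines(cfg, profiles)
        for tl in tls:
            tr = tl.day_truth
            assert tr["onset_min"].sub(tr["day"] * 1440).nunique() == 1
            assert tr["offset_min"].sub(tr["day"] * 1440).nunique() == 1

    def test_zero_activity_level_means_no_active_daytime_slots(self):
        cfg = CohortConfig(n_participants=2, n_days=5, missingness_prob=0.0, seed=1)
        profiles = _profiles(cfg, activity_level=0.0)
        tls = generate_timelines(cfg, profiles)
        for tl in tls:
            assert not np.any(tl.state == ACTIVE)

    def test_fixed_seed_reproduces_timelines(self):
        cfg = CohortConfig(n_participants=3, n_days=6, seed=9)
        a = generate_timelines(cfg, _profiles(cfg))
        b = generate_timelines(cfg, _profiles(cfg))
        for x, y in zip(a, b):
            assert np.array_equal(x.state, y.state)
            assert np.array_equal(x.observed, y.observed)
            pd.testing.assert_frame_equal(x.day_truth, y.day_truth)

    def test_slot_spacing_and_count(self):
        cfg = CohortConfig(n_participants=1, n_days=3, seed=0)
        (tl,) = generate_timelines(cfg, _profiles(cfg))
        assert np.all(np.diff(tl.slot_min) == cfg.obs_interval_min)
        assert tl.slot_min.size == 3 * 24 * 60 // cfg.obs_interval_min

    def test_nightly_block_is_longest_nonactive_stretch(self):
        cfg = CohortConfig(n_participants=4, n_days=10, missingness_prob=0.0, seed=3)
        for tl in generate_timelines(cfg, _profiles(cfg)):
            for _, row in tl.day_truth.iterrows():
                d = int(row["day"])
                sel = (tl.slot_min // 1440) == d
                mm = tl.slot_min[sel]
                inside = (mm >= row["onset_min"]) & (mm <= row["offset_min"])
                assert not np.any(tl.state[sel][inside] == ACTIVE)


class TestBursts:
    def test_noise_free_still_burst_has_zero_deviation(self):
        cfg = CohortConfig(still_noise_sd=0.0)
        b = synthesize_burst("still", cfg, np.random.default_rng(0))
        feats = extract_features(b)
        assert feats.mean_mag == pytest.approx(0.0, abs=1e-9)

    def test_active_dominant_frequency_in_step_band(self, rng):
        # independent periodogram oracle: raw FFT of the deviation magnitude
        cfg = CohortConfig()
        hits = 0
        for _ in range(25):
            b = synthesize_burst("active", cfg, rng)
            dev = b.xyz - b.xyz.mean(axis=0)
            mag = np.linalg.norm(dev, axis=1)
            grid = np.arange(0, b.t[-1], 1 / 32.0)
            x = np.interp(grid, b.t, mag)
            x -= x.mean()
            spec = np.abs(np.fft.rfft(x)) ** 2
            freqs = np.fft.rfftfreq(x.size, 1 / 32.0)
            dom = freqs[1:][np.argmax(spec[1:])]
            if 1.5 - 0.5 <= dom <= 2.5 + 0.5:
                hits += 1
        assert hits >= 23

    def test_same_seed_same_samples(self):
        cfg = CohortConfig()
        a = synthesize_burst("active", cfg, np.random.default_rng(5))
        b = synthesize_burst("active", cfg, np.random.default_rng(5))
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.xyz, b.xyz)

    def test_unknown_state_raises(self):
        with pytest.raises(ValueError):
            synthesize_burst("vehicle", CohortConfig(), np.random.default_rng(0))

    def test_burst_duration_and_ordering(self, rng):
        cfg = CohortConfig()
        b = synthesize_burst("other", cfg, rng)
        assert np.all(np.diff(b.t) > 0)
        assert b.t[-1] == pytest.approx(cfg.burst_seconds, abs=0.3)

    def test_state_separability_of_deviation_magnitude(self, rng):
        cfg = CohortConfig()
        means = {}
        for state in ("still", "active", "other"):
            vals = []
            for _ in range(200):
                b = synthesize_burst(state, cfg, rng)
                dev = b.xyz - b.xyz.mean(axis=0)
                vals.append(np.linalg.norm(dev, axis=1).mean())
            means[state] = np.mean(vals)
        assert means["active"] > means["other"] > means["still"]


class TestWellbeing:
    def test_deterministic_generator_gives_constant_responses(self):
        cfg = CohortConfig(n_participants=2, n_days=4, survey_response_prob=1.0, seed=2)
        profiles = _profiles(cfg)
        tls = generate_timelines(cfg, profiles)
        zeros = dict(
            beta_day_of_study=0.0,
            beta_weekday=0.0,
            beta_sleep=0.0,
            beta_activity=0.0,
            beta_stillness=0.0,
            intercept=5.0,
            random_effect_sds=(0.0,) * 6,
            residual_sd=0.0,
            response_sd=0.0,
        )
        coeffs = (
            GenerativeCoefficients.mood_defaults(**zeros),
            GenerativeCoefficients.energy_defaults(**zeros),
        )
        ema, _ = generate_wellbeing(tls, profiles, coeffs, cfg)
        assert (ema["mood"] == 5).all()
        assert (ema["energy"] == 5).all()

    def test_strong_activity_effect_yields_positive_correlation(self):
        cfg = CohortConfig(n_participants=20, n_days=28, seed=7, survey_response_prob=1.0)
        coeffs = (
            GenerativeCoefficients.mood_defaults(beta_activity=1.5, residual_sd=0.3),
            GenerativeCoefficients.energy_defaults(),
        )
        profiles = generate_profiles(cfg, coeffs)
        tls = generate_timelines(cfg, profiles)
        ema, _ = generate_wellbeing(tls, profiles, coeffs, cfg)
        dates = pd.to_datetime(ema["t_unix_s"], unit="s").dt.normalize()
        ema = ema.assign(day=(dates - pd.Timestamp(cfg.start_date)).dt.days)
        daily = ema.groupby(["participant_id", "day"])["mood"].mean().reset_index()
        truth = pd.concat(
            [t.day_truth.assign(participant_id=t.participant_id) for t in tls], ignore_index=True
        )
        j = daily.merge(truth, on=["participant_id", "day"])
        assert np.corrcoef(j["activity_frac"], j["mood"])[0, 1] > 0.2

    def test_survey_counts_and_windows(self, small_cohort):
        cfg = small_cohort["config"]
        ema = small_cohort["ema"]
        ts = pd.to_datetime(ema["t_unix_s"], unit="s")
        clock = ts.dt.hour * 60 + ts.dt.minute + ts.dt.second / 60.0
        in_any = np.zeros(len(ema), dtype=bool)
        for lo, hi in cfg.survey_windows:
            in_any |= (clock >= lo) & (clock <= hi)
        assert in_any.all()
        per_day = ema.groupby(["participant_id", ts.dt.normalize()]).size()
        assert per_day.max() <= len(cfg.survey_windows)
        assert ema["mood"].between(1, 9).all()
        assert ema["energy"].between(1, 9).all()

    def test_generative_recovery_of_latent_level(self):
        """With no random effects and vanishing noise, daily mean mood equals
        the latent linear predictor up to rounding error <= 0.5."""
        cfg = CohortConfig(n_participants=3, n_days=10, survey_response_prob=1.0, seed=4)
        quiet = dict(random_effect_sds=(0.0,) * 6, residual_sd=1e-9, response_sd=0.0)
        coeffs = (
            GenerativeCoefficients.mood_defaults(**quiet),
            GenerativeCoefficients.energy_defaults(**quiet),
        )
        profiles = generate_profiles(cfg, coeffs)
        tls = generate_timelines(cfg, profiles)
        ema, latent = generate_wellbeing(tls, profiles, coeffs, cfg)
        dates = pd.to_datetime(ema["t_unix_s"], unit="s").dt.normalize()
        ema = ema.assign(day=(dates - pd.Timestamp(cfg.start_date)).dt.days)
        daily = ema.groupby(["participant_id", "day"])["mood"].mean().reset_index()
        j = daily.merge(latent, on=["participant_id", "day"])
        assert (j["mood"] - j["latent_mood"]).abs().max() <= 0.5

    def test_seed_streams_are_distinct(self):
        cfg = CohortConfig(seed=5)
        a = _rng_for(cfg, 0).random(4)
        b = _rng_for(cfg, 1).random(4)
        assert not np.allclose(a, b)
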