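"""Synthetic cohort generator.

Emulates the three inputs of a smartphone well-being field study that
deposited no data:

1. raw accelerometer *bursts* (3 s of tri-axial samples every 5 minutes),
2. daily ecological momentary assessment (EMA) surveys — mood and energy on
   9-point Likert scales, up to 4 per day in fixed clock windows, and
3. an activity-labeled burst set for classifier training.

Each participant follows a nightly sleep schedule (one contiguous still
block per night, onset/offset jittered day to day and snapped to the
observation grid) and a daytime activity process (each daytime slot is
physically active with a per-day probability). Slots inside the nightly
block are *still* with a per-night stillness probability, modelling sleep
disturbance; everything else is *other*. The slots bordering the nightly
block are forced active — people move when going to bed and when getting
up — which makes the block recoverable as the longest not-active run.

Well-being is generated by the mixed-effects model the analysis fits:
a latent daily level ``intercept + sum_k (beta_k + b_ik) x_ik + eps`` with
within-person standardized true behavior measures and [0, 1]-scaled time
covariates, per-person random effects ``b_i``, and daily residual noise.
Individual survey responses add response noise and are rounded (half-up)
and clipped to the 1..9 scale. Default coefficients are the effect sizes
the population analysis reports for mood and energy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._timebase import (
    DAY_MIN,
    anchor_epoch_s,
    clock_to_axis_min,
    weekday_of_day,
)
from .features import AccelBurst

STATES = ("still", "active", "other")
STATE_CODE = {name: i for i, name in enumerate(STATES)}
STILL, ACTIVE, OTHER = 0, 1, 2

#: model terms, in the canonical order used throughout the package
MODEL_TERMS = (
    "intercept",
    "day_of_study",
    "weekday",
    "sleep_duration",
    "daytime_activity",
    "nighttime_stillness",
)


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Survey windows are (start, end) clock minutes since midnight, disjoint,
    within 08:00-22:00. ``missingness_prob`` drops whole bursts
    independently, the dominant failure mode of field collection.
    """

    n_participants: int = 20
    n_days: int = 56
    burst_rate_hz: float = 32.0
    burst_seconds: float = 3.0
    obs_interval_min: int = 5
    survey_windows: tuple = ((480, 660), (660, 840), (840, 1020), (1020, 1320))
    missingness_prob: float = 0.05
    survey_response_prob: float = 0.8
    start_date: str = "2017-01-09"  # a Monday
    seed: int = 0
    #: longest stretch of waking time without any physically active burst;
    #: keeps daytime sedentary runs shorter than any nightly block
    max_sedentary_min: int = 90
    # burst noise structure by state (m/s^2)
    still_noise_sd: float = 0.05
    other_noise_sd: tuple = (0.2, 0.8)
    active_amp: tuple = (1.5, 3.5)
    active_noise_sd: float = 0.3
    step_freq_hz: tuple = (1.5, 2.5)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.burst_rate_hz < 10:
            raise ConfigError("burst_rate_hz must be >= 10")
        if not (0 <= self.missingness_prob < 1):
            raise ConfigError("missingness_prob must be in [0, 1)")
        if not (0 <= self.survey_response_prob <= 1):
            raise ConfigError("survey_response_prob must be in [0, 1]")
        if self.obs_interval_min < 1 or DAY_MIN % self.obs_interval_min:
            raise ConfigError("obs_interval_min must be >= 1 and divide 1440")
        wins = sorted(self.survey_windows)
        for lo, hi in wins:
            if not (480 <= lo < hi <= 1320):
                raise ConfigError("survey windows must lie within 08:00-22:00")
        for (_, hi), (lo, _) in zip(wins, wins[1:]):
            if lo < hi:
                raise ConfigError("survey windows must be disjoint")


@dataclass
class GenerativeCoefficients:
    """Fixed effects, random-effect scales and noise of the generative model.

    Slopes apply to within-person standardized behavior measures and
    [0, 1]-scaled time covariates, so they are on the Likert-point scale.
    """

    outcome: str
    intercept: float
    beta_day_of_study: float
    beta_weekday: float
    beta_sleep: float
    beta_activity: float
    beta_stillness: float
    random_effect_sds: tuple = (0.15,) * 6  # one per MODEL_TERMS entry
    residual_sd: float = 1.0
    response_sd: float = 0.3

    def validate(self) -> None:
        if self.residual_sd < 0 or self.response_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if len(self.random_effect_sds) != len(MODEL_TERMS):
            raise ConfigError(f"random_effect_sds must have {len(MODEL_TERMS)} entries")
        if any(s < 0 for s in self.random_effect_sds):
            raise ConfigError("random_effect_sds must be >= 0")

    def betas(self) -> np.ndarray:
        """Coefficient vector in MODEL_TERMS order (intercept first)."""
        return np.array(
            [
                self.intercept,
                self.beta_day_of_study,
                self.beta_weekday,
                self.beta_sleep,
                self.beta_activity,
                self.beta_stillness,
            ]
        )

    @classmethod
    def mood_defaults(cls, **overrides) -> "GenerativeCoefficients":
        """Mood model effect sizes reported by the population analysis."""
        kw = dict(
            outcome="mood",
            intercept=5.056,
            beta_day_of_study=-0.059,
            beta_weekday=0.040,
            beta_sleep=0.072,
            beta_activity=0.097,
            beta_stillness=0.040,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def energy_defaults(cls, **overrides) -> "GenerativeCoefficients":
        """Energy model effect sizes reported by the population analysis."""
        kw = dict(
            outcome="energy",
            intercept=5.686,
            beta_day_of_study=-0.304,
            beta_weekday=0.196,
            beta_sleep=-0.027,
            beta_activity=0.182,
            beta_stillness=0.024,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class ParticipantProfile:
    """Per-person schedule, behavior levels and model random effects.

    Clock times are minutes on the night axis (minutes since 21:00), so
    sleep onset ~150 means 23:30 and offset ~630 means 07:30.
    """

    participant_id: str
    sleep_onset_mean: float = 150.0
    sleep_offset_mean: float = 630.0
    schedule_jitter_sd: float = 30.0
    activity_level: float = 0.3
    activity_day_sd: float = 0.08
    stillness_level: float = 0.88
    stillness_day_sd: float = 0.06
    random_effects: dict = field(default_factory=dict)  # outcome -> array over MODEL_TERMS


@dataclass
class StateTimeline:
    """Ground-truth state sequence for one participant.

    ``slot_min`` are absolute night-axis minutes of the observation slots,
    ``state`` the true state codes, ``observed`` the post-dropout mask.
    ``day_truth`` holds per-day generative truth: nightly block bounds,
    realized sleep hours, activity and stillness fractions.
    """

    participant_id: str
    slot_min: np.ndarray
    state: np.ndarray
    observed: np.ndarray
    day_truth: pd.DataFrame


def _rng_for(config: CohortConfig, stream: int) -> np.random.Generator:
    """Deterministic per-stage child generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[stream])


def generate_profiles(
    config: CohortConfig,
    coeffs: tuple[GenerativeCoefficients, ...] = (),
    rng: np.random.Generator | None = None,
) -> list[ParticipantProfile]:
    """Draw per-person schedules, activity levels and random effects."""
    config.validate()
    rng = rng if rng is not None else _rng_for(config, 0)
    if not coeffs:
        coeffs = (GenerativeCoefficients.mood_defaults(), GenerativeCoefficients.energy_defaults())
    profiles = []
    for i in range(config.n_participants):
        re = {}
        for c in coeffs:
            c.validate()
            re[c.outcome] = rng.normal(0.0, np.asarray(c.random_effect_sds, dtype=float))
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i:03d}",
                sleep_onset_mean=float(np.clip(rng.normal(150.0, 40.0), 30.0, 330.0)),
                sleep_offset_mean=float(np.clip(rng.normal(630.0, 40.0), 480.0, 780.0)),
                activity_level=float(rng.uniform(0.15, 0.45)),
                stillness_level=float(np.clip(rng.normal(0.88, 0.04), 0.70, 0.97)),
                random_effects=re,
            )
        )
    return profiles


def generate_timelines(
    config: CohortConfig,
    profiles: list[ParticipantProfile],
    rng: np.random.Generator | None = None,
) -> list[StateTimeline]:
    """Simulate per-slot true states and per-day truth for every participant.

    Each participant-day has one contiguous nightly block whose onset and
    offset are jittered by ``schedule_jitter_sd`` and snapped to the
    observation grid; daytime slots are active with a per-day probability;
    dropout removes whole slots independently with ``missingness_prob``.
    """
    config.validate()
    if len(profiles) != config.n_participants:
        raise ConfigError("profiles length must equal n_participants")
    rng = rng if rng is not None else _rng_for(config, 1)
    step = config.obs_interval_min
    n_days = config.n_days
    slot_min = np.arange(0, n_days * DAY_MIN, step)
    mm = slot_min % DAY_MIN
    dd = slot_min // DAY_MIN

    timelines = []
    for prof in profiles:
        # nightly block bounds, snapped to the slot grid
        onset = rng.normal(prof.sleep_onset_mean, prof.schedule_jitter_sd, n_days)
        offset = rng.normal(prof.sleep_offset_mean, prof.schedule_jitter_sd, n_days)
        onset = np.clip(np.round(onset / step) * step, step, 420.0)
        offset = np.clip(np.round(offset / step) * step, onset + 12 * step, 960.0)

        if prof.activity_level == 0.0:
            p_act = np.zeros(n_days)
        else:
            p_act = np.clip(rng.normal(prof.activity_level, prof.activity_day_sd, n_days), 0.02, 0.95)
        s_night = np.clip(rng.normal(prof.stillness_level, prof.stillness_day_sd, n_days), 0.0, 1.0)

        in_block = (mm >= onset[dd]) & (mm <= offset[dd])
        # daytime slots before the night's onset belong to the previous day's
        # waking period (its evening); clip day -1 to day 0
        act_day = np.where(mm >= offset[dd], dd, dd - 1).clip(0, n_days - 1)

        u = rng.random(slot_min.size)
        state = np.where(u < p_act[act_day], ACTIVE, OTHER).astype(np.int8)
        u2 = rng.random(slot_min.size)
        state[in_block] = np.where(u2[in_block] < s_night[dd[in_block]], STILL, OTHER)

        # force the slots bordering each nightly block to be active so the
        # block is exactly the longest not-active run
        # people move when going to bed and getting up, and rarely stay
        # perfectly sedentary for hours while awake: anchor active bursts
        # at the block borders and at least every max_sedentary_min of
        # waking time (skipped for zero-activity profiles)
        k_anchor = max(config.max_sedentary_min // step, 1)
        for d in range(n_days):
            i0 = int((d * DAY_MIN + onset[d]) // step)
            i1 = int((d * DAY_MIN + offset[d]) // step)
            if i0 - 1 >= 0 and p_act[max(d - 1, 0)] > 0:
                state[i0 - 1] = ACTIVE
            if i1 + 1 < state.size and p_act[d] > 0:
                state[i1 + 1] = ACTIVE
            if p_act[d] <= 0:
                continue
            wake_start = i1 + 1
            if d + 1 < n_days:
                wake_end = int(((d + 1) * DAY_MIN + onset[d + 1]) // step) - 1
            else:
                wake_end = state.size - 1
            for j in range(wake_start + k_anchor, wake_end + 1, k_anchor):
                state[j] = ACTIVE
            if d == 0:
                for j in range(k_anchor - 1, i0 - 1, k_anchor):
                    state[j] = ACTIVE

        observed = (
            rng.random(slot_min.size) >= config.missingness_prob
            if config.missingness_prob > 0
            else np.ones(slot_min.size, dtype=bool)
        )

        is_daytime = ~in_block
        truth_rows = []
        for d in range(n_days):
            day_slots = is_daytime & (act_day == d)
            block_slots = in_block & (dd == d)
            truth_rows.append(
                {
                    "day": d,
                    "onset_min": float(d * DAY_MIN + onset[d]),
                    "offset_min": float(d * DAY_MIN + offset[d]),
                    "sleep_h": float((offset[d] - onset[d]) / 60.0),
                    "activity_frac": float((state[day_slots] == ACTIVE).mean())
                    if day_slots.any()
                    else np.nan,
                    "still_frac": float((state[block_slots] == STILL).mean())
                    if block_slots.any()
                    else np.nan,
                    "activity_level": float(p_act[d]),
                    "stillness_level": float(s_night[d]),
                }
            )
        timelines.append(
            StateTimeline(
                participant_id=prof.participant_id,
                slot_min=slot_min.copy(),
                state=state,
                observed=observed,
                day_truth=pd.DataFrame(truth_rows),
            )
        )
    return timelines


def synthesize_burst(
    state: str, config: CohortConfig, rng: np.random.Generator
) -> AccelBurst:
    """Raw tri-axial samples for one burst in the given true state.

    * still: gravity (9.81 m/s^2, random orientation) + small white noise;
    * active: gravity + a mostly-vertical sinusoidal locomotion component
      (fundamental 1.5-2.5 Hz with a first harmonic) + noise;
    * other: gravity + low-amplitude broadband noise (handling, fidgeting).

    Sample times are jittered by +/-20% of the nominal period to exercise
    the resampling path downstream.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    n = int(round(config.burst_seconds * config.burst_rate_hz)) + 1
    dt = 1.0 / config.burst_rate_hz
    t = np.arange(n) * dt + rng.uniform(-0.2, 0.2, n) * dt
    t -= t[0]

    g_dir = rng.normal(size=3)
    g_dir /= np.linalg.norm(g_dir)
    g = 9.81 * g_dir
    xyz = np.tile(g, (n, 1))

    if state == "still":
        xyz = xyz + rng.normal(0.0, config.still_noise_sd, (n, 3))
    elif state == "other":
        amp = rng.uniform(*config.other_noise_sd)
        xyz = xyz + rng.normal(0.0, amp, (n, 3))
    else:  # active: a stride model with step rate f0
        # lateral sway swings once per stride (f0/2); the vertical bounce
        # hits once per step (f0). The norm taken downstream squares the
        # sway, so the deviation-magnitude spectrum peaks at f0.
        perp = rng.normal(size=3)
        perp -= perp @ g_dir * g_dir
        perp /= max(np.linalg.norm(perp), 1e-12)
        u_bounce = g_dir + 0.25 * perp
        u_bounce /= np.linalg.norm(u_bounce)
        u_sway = perp
        f0 = rng.uniform(*config.step_freq_hz)
        amp = rng.uniform(*config.active_amp)
        phase = rng.uniform(0, 2 * np.pi, 2)
        sway = amp * np.sin(np.pi * f0 * t + phase[0])
        bounce = 0.4 * amp * np.sin(2 * np.pi * f0 * t + phase[1])
        xyz = (
            xyz
            + sway[:, None] * u_sway
            + bounce[:, None] * u_bounce
            + rng.normal(0.0, config.active_noise_sd, (n, 3))
        )

    return AccelBurst(participant_id="", burst_id="", t=t, xyz=xyz)


def generate_labeled_bursts(
    config: CohortConfig,
    n_participants: int = 6,
    n_per_state: int = 60,
    rng: np.random.Generator | None = None,
) -> tuple[list[AccelBurst], pd.DataFrame]:
    """Balanced activity-labeled burst set for classifier training.

    The study's auxiliary training data composition is unknown; classes are
    balanced here as the neutral choice.
    """
    config.validate()
    rng = rng if rng is not None else _rng_for(config, 2)
    bursts: list[AccelBurst] = []
    labels = []
    for i in range(n_participants):
        pid = f"train{i:02d}"
        for state in STATES:
            for k in range(n_per_state):
                b = synthesize_burst(state, config, rng)
                b.participant_id = pid
                b.burst_id = f"{pid}_{state}_{k:04d}"
                b.t_unix_s = float(len(bursts)) * config.obs_interval_min * 60.0
                bursts.append(b)
                labels.append({"participant_id": pid, "burst_id": b.burst_id, "state": state})
    return bursts, pd.DataFrame(labels)


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    """Within-person z-score per column; a zero-variance column maps to 0."""
    x = np.asarray(x, dtype=float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out


def _likert(x: np.ndarray) -> np.ndarray:
    """Round half-up and clip to the 9-point scale."""
    return np.clip(np.floor(x + 0.5), 1, 9).astype(int)


def generate_wellbeing(
    timelines: list[StateTimeline],
    profiles: list[ParticipantProfile],
    coeffs: tuple[GenerativeCoefficients, GenerativeCoefficients],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate EMA survey responses from the generative mixed model.

    Returns ``(ema, latent)``: the survey table (participant_id, t_unix_s,
    mood, energy) and the per-day latent truth (standardized covariates and
    latent levels) for use as a test oracle.
    """
    config.validate()
    for c in coeffs:
        c.validate()
    rng = rng if rng is not None else _rng_for(config, 3)
    epoch0 = anchor_epoch_s(config.start_date)
    n_days = config.n_days
    day_s = np.arange(n_days) / max(n_days - 1, 1)
    weekday = np.array([weekday_of_day(config.start_date, d) for d in range(n_days)])
    weekday_s = weekday / 6.0

    ema_rows = []
    latent_rows = []
    by_pid = {p.participant_id: p for p in profiles}
    for tl in timelines:
        prof = by_pid[tl.participant_id]
        truth = tl.day_truth
        xz = _standardize_columns(
            truth[["sleep_h", "activity_frac", "still_frac"]].to_numpy()
        )
        # covariate matrix in MODEL_TERMS order (after the intercept)
        X = np.column_stack([day_s, weekday_s, xz])
        latents = {}
        for c in coeffs:
            b = np.asarray(prof.random_effects.get(c.outcome, np.zeros(6)), dtype=float)
            beta = c.betas()
            eps = rng.normal(0.0, c.residual_sd, n_days) if c.residual_sd > 0 else np.zeros(n_days)
            latents[c.outcome] = (beta[0] + b[0]) + X @ (beta[1:] + b[1:]) + eps
        for d in range(n_days):
            latent_rows.append(
                {
                    "participant_id": tl.participant_id,
                    "day": d,
                    "day_s": day_s[d],
                    "weekday_s": weekday_s[d],
                    "sleep_z": xz[d, 0],
                    "activity_z": xz[d, 1],
                    "stillness_z": xz[d, 2],
                    **{f"latent_{k}": float(v[d]) for k, v in latents.items()},
                }
            )
            for lo, hi in config.survey_windows:
                if rng.random() >= config.survey_response_prob:
                    continue
                clock = rng.uniform(lo, hi)
                t_unix = epoch0 + clock_to_axis_min(d, clock) * 60.0
                row = {"participant_id": tl.participant_id, "t_unix_s": float(t_unix)}
                for c in coeffs:
                    noise = rng.normal(0.0, c.response_sd) if c.response_sd > 0 else 0.0
                    row[c.outcome] = int(_likert(np.array([latents[c.outcome][d] + noise]))[0])
                ema_rows.append(row)
    ema = pd.DataFrame(ema_rows)
    if not ema.empty:
        ema = ema.sort_values(["participant_id", "t_unix_s"]).reset_index(drop=True)
    return ema, pd.DataFrame(latent_rows)


def perfect_state_calls(timeline: StateTimeline, config: CohortConfig) -> pd.DataFrame:
    """State-call table from the ground truth (an error-free classifier).

    Only observed (non-dropped) slots appear; probabilities are 0/1.
    """
    epoch0 = anchor_epoch_s(config.start_date)
    m = timeline.slot_min[timeline.observed]
    st = timeline.state[timeline.observed]
    return pd.DataFrame(
        {
            "participant_id": timeline.participant_id,
            "burst_id": [f"{timeline.participant_id}_b{int(v):07d}" for v in m],
            "t_unix_s": epoch0 + m * 60.0,
            "p_still": (st == STILL).astype(float),
            "p_active": (st == ACTIVE).astype(float),
            "is_still": st == STILL,
            "is_active": st == ACTIVE,
        }
    )


def cohort_accel_frame(
    timelines: list[StateTimeline],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Raw accelerometer sample table for all observed slots of a cohort.

    One row per sample; intended for small cohorts (the table grows as
    participants x days x 288 slots x ~97 samples).
    """
    rng = rng if rng is not None else _rng_for(config, 4)
    epoch0 = anchor_epoch_s(config.start_date)
    frames = []
    for tl in timelines:
        for m, st, obs in zip(tl.slot_min, tl.state, tl.observed):
            if not obs:
                continue
            b = synthesize_burst(STATES[st], config, rng)
            t0 = epoch0 + m * 60.0
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": tl.participant_id,
                        "burst_id": f"{tl.participant_id}_b{int(m):07d}",
                        "t_unix_s": t0 + b.t,
                        "x": b.xyz[:, 0],
                        "y": b.xyz[:, 1],
                        "z": b.xyz[:, 2],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["participant_id", "burst_id", "t_unix_s", "x", "y", "z"])
    return pd.concat(frames, ignore_index=True)


def bursts_to_accel_frame(bursts: list[AccelBurst]) -> pd.DataFrame:
    """Stack AccelBursts into the raw-sample table layout."""
    frames = []
    for b in bursts:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": b.participant_id,
                    "burst_id": b.burst_id,
                    "t_unix_s": b.t_unix_s + b.t,
                    "x": b.xyz[:, 0],
                    "y": b.xyz[:, 1],
                    "z": b.xyz[:, 2],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def truth_payload(
    config: CohortConfig,
    profiles: list[ParticipantProfile],
    timelines: list[StateTimeline],
    coeffs: tuple[GenerativeCoefficients, ...],
) -> dict:
    """JSON-serializable generative truth (coefficients + per-day measures)."""
    return {
        "config": asdict(config),
        "coefficients": [asdict(c) for c in coeffs],
        "random_effects": {
            p.participant_id: {k: list(map(float, v)) for k, v in p.random_effects.items()}
            for p in profiles
        },
        "day_truth": {
            tl.participant_id: tl.day_truth.to_dict(orient="list") for tl in timelines
        },
    }


def write_truth_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
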