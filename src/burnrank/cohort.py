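"""Synthetic longitudinal cohort generator.

Emulates a workplace wearable-monitoring study: ~200 workers followed for
~9 months with daily wearable-derived summaries (sleep, cardiac, stress,
activity), monthly 14-item burnout surveys (SMBM) with sparse completion,
and realistic day/night adherence gaps.

The generative model
--------------------
Each participant carries a latent burnout-severity process

    s_it = b_i + w_it

where ``b_i ~ N(0, sigma_b^2)`` is a stable person-level trait and ``w_it``
is a stationary mean-reverting Gaussian walk (AR(1)) with marginal variance
``sigma_w^2``, so severity drifts slowly over weeks without diverging.

Each daily feature ``f`` is built on a standardized latent scale as

    z_ift = u_if + c * beta_f * s_it + e_ift

with subject effect ``u_if``, i.i.d. daily noise ``e_ift``, and coupling
strength ``c = latent_coupling``.  The variances of ``u`` and ``e`` are
chosen so the between/(between+within) ratio equals ``icc_targets[f]``
exactly, *including* the severity contribution; at ``c = 0`` physiology is
statistically independent of the surveys by construction.

Survey items are discretized latent responses ``gamma * s_it`` plus item
noise, clipped to the 1-7 Likert range; subscale scores are item means.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    CohortConfig,
    ConfigError,
    DEFAULT_SMBM_MAP,
    TIME_VARYING_FEATURES,
)

# ---------------------------------------------------------------------------
# Calibration constants (fixed, documented in docs/methods.md)
# ---------------------------------------------------------------------------

SIGMA_B = 1.0  # sd of the stable severity trait
SIGMA_W = 0.65  # marginal sd of the severity walk
AR_RHO = 0.98  # day-to-day autocorrelation of the walk

ITEM_GAMMA = 1.1  # severity loading of survey items
ITEM_NOISE_SD = 0.8
ITEM_INTERCEPT = 3.2

#: Severity loading per feature on the standardized scale. Higher severity
#: means shorter/lighter sleep, higher heart rates, more stress, more
#: sedentary time.
FEATURE_BETA: Dict[str, float] = {
    "total_sleep_time": -0.35,
    "waso": 0.35,
    "restorative_sleep_pct": -0.35,
    "median_waking_hr": 0.35,
    "rest_hr": 0.35,
    "overnight_stress": 0.35,
    "sedentary_pct": 0.35,
}

#: Location/scale mapping from the standardized latent to feature units.
FEATURE_LOC_SCALE: Dict[str, Tuple[float, float]] = {
    "total_sleep_time": (420.0, 50.0),  # minutes
    "waso": (45.0, 18.0),               # minutes
    "restorative_sleep_pct": (40.0, 8.0),
    "median_waking_hr": (78.0, 7.0),    # bpm
    "rest_hr": (56.0, 6.0),             # bpm
    "overnight_stress": (30.0, 10.0),   # Garmin-like 0-100 score
    "sedentary_pct": (60.0, 9.0),
}

SLEEP_FEATURES = (
    "total_sleep_time",
    "waso",
    "restorative_sleep_pct",
    "rest_hr",
    "overnight_stress",
)
DAYTIME_FEATURES = ("median_waking_hr", "sedentary_pct")

MCAR_EXTRA_MISSING = 0.02  # extra completely-at-random dropout per cell
SHORT_SESSION_PROB = 0.03  # sleep sessions truncated below two hours


def score_smbm(
    item_responses: Sequence[int],
    smbm_map: Dict[str, Tuple[int, ...]] | None = None,
) -> Tuple[float, float, float, float]:
    """Score one 14-item SMBM response.

    Returns ``(pf, cw, ee, overall)`` where each subscale is the mean of its
    items and the overall score is the item-count-weighted average of the
    subscales — equivalently the mean of all 14 items.

    Raises
    ------
    ValueError
        If there are not exactly 14 responses or any lies outside 1..7.
    """
    items = np.asarray(item_responses, dtype=float)
    if items.shape != (14,):
        raise ValueError(f"expected exactly 14 item responses, got shape {items.shape}")
    if not np.all((items >= 1) & (items <= 7)):
        raise ValueError("item responses must lie in [1, 7]")
    if not np.allclose(items, np.round(items)):
        raise ValueError("item responses must be integers")
    smbm_map = smbm_map or DEFAULT_SMBM_MAP
    pf = float(items[list(smbm_map["pf"])].mean())
    cw = float(items[list(smbm_map["cw"])].mean())
    ee = float(items[list(smbm_map["ee"])].mean())
    overall = float(items.mean())
    return pf, cw, ee, overall


def _simulate_severity(rng: np.random.Generator, n_days: int) -> np.ndarray:
    """Stationary AR(1) walk with marginal sd SIGMA_W."""
    innov_sd = SIGMA_W * np.sqrt(1.0 - AR_RHO**2)
    w = np.empty(n_days)
    w[0] = rng.normal(0.0, SIGMA_W)
    shocks = rng.normal(0.0, innov_sd, size=n_days - 1)
    for t in range(1, n_days):
        w[t] = AR_RHO * w[t - 1] + shocks[t - 1]
    return w


def _variance_split(icc: float, coupling: float, beta: float) -> Tuple[float, float]:
    """Subject-effect and daily-noise sds so total between/within hits `icc`."""
    sev_between = (coupling * beta) ** 2 * SIGMA_B**2
    sev_within = (coupling * beta) ** 2 * SIGMA_W**2
    var_u = max(icc - sev_between, 1e-4)
    var_e = max((1.0 - icc) - sev_within, 1e-4)
    return np.sqrt(var_u), np.sqrt(var_e)


def generate_cohort(
    config: CohortConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns
    -------
    profiles : DataFrame
        One row per participant: the eight time-invariant covariates plus
        simulator-only latent severity traits.
    daily : DataFrame
        One row per participant-day: wear fraction, the seven time-varying
        features (NaN = missing), and sleep-session metadata.
    assessments : DataFrame
        One row per completed survey: the 14 item responses, subscale and
        overall scores, and an ``is_baseline`` flag (first survey).
    """
    if not isinstance(config, CohortConfig):
        raise ConfigError("generate_cohort expects a CohortConfig")
    rng = np.random.default_rng(config.seed)
    n, days = config.n_participants, config.study_days
    c = config.latent_coupling

    # --- profiles -----------------------------------------------------------
    profiles = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "gender": rng.binomial(1, 0.40, n),
            "age": np.clip(rng.normal(38.0, 8.0, n), 18.0, 65.0).round(1),
            "bmi": np.clip(rng.normal(25.0, 3.5, n), 16.0, 45.0).round(1),
            "relationship": rng.binomial(1, 0.60, n),
            "seniority": rng.binomial(1, 0.30, n),
            "work_type": rng.binomial(1, 0.50, n),
            "shift_work": rng.binomial(1, 0.25, n),
            "site": rng.binomial(1, 0.50, n),
        }
    )
    trait = rng.normal(0.0, SIGMA_B, n)
    profiles["latent_severity_baseline"] = trait
    profiles["latent_severity_walk_sd"] = SIGMA_W

    # Per-feature variance split, shared across participants.
    splits = {
        f: _variance_split(config.icc_targets.get(f, 0.5), c, FEATURE_BETA[f])
        for f in TIME_VARYING_FEATURES
    }

    # Follow-up survey days: every survey_interval_days after baseline day 0.
    followup_days = list(
        range(config.survey_interval_days, days, config.survey_interval_days)
    )

    daily_rows = []
    assess_rows = []
    for i in range(n):
        pid = profiles.at[i, "participant_id"]
        walk = _simulate_severity(rng, days)
        severity = trait[i] + walk  # s_it, length `days`

        # Subject effects per feature.
        u = {f: rng.normal(0.0, splits[f][0]) for f in TIME_VARYING_FEATURES}

        # Latent standardized features for every day.
        z = {}
        for f in TIME_VARYING_FEATURES:
            noise = rng.normal(0.0, splits[f][1], days)
            z[f] = u[f] + c * FEATURE_BETA[f] * severity + noise

        # --- adherence ------------------------------------------------------
        p_day = np.full(days, config.wear_adherence_rate)
        sess_p = min(
            1.0,
            config.night_adherence_rate
            / ((1.0 - config.manual_sleep_prob) * (1.0 - SHORT_SESSION_PROB)),
        )
        p_sess = np.full(days, sess_p)
        if config.severity_linked_missingness > 0:
            # Higher severity lowers adherence through a logistic shift.
            lam = config.severity_linked_missingness
            for p in (p_day, p_sess):
                logit = np.log(p / (1.0 - p + 1e-12)) - lam * severity
                p[:] = 1.0 / (1.0 + np.exp(-logit))

        day_adherent = rng.random(days) < p_day
        wear_fraction = np.where(
            day_adherent,
            rng.uniform(0.70, 1.0, days),
            rng.uniform(0.0, 0.70, days),
        )
        session_present = rng.random(days) < p_sess
        manual = session_present & (rng.random(days) < config.manual_sleep_prob)
        short = session_present & (rng.random(days) < SHORT_SESSION_PROB)

        # --- observed features ---------------------------------------------
        feats = {}
        for f in TIME_VARYING_FEATURES:
            loc, scale = FEATURE_LOC_SCALE[f]
            x = loc + scale * z[f]
            if f in ("restorative_sleep_pct", "sedentary_pct", "overnight_stress"):
                x = np.clip(x, 0.0, 100.0)
            elif f == "waso":
                x = np.clip(x, 0.0, None)
            feats[f] = x

        night_ok = session_present & ~manual & ~short
        main_sleep = np.full(days, np.nan)
        ok = night_ok
        main_sleep[ok] = (
            feats["total_sleep_time"][ok]
            + feats["waso"][ok]
            + rng.normal(0.0, 15.0, int(ok.sum()))
        )
        main_sleep[ok] = np.clip(main_sleep[ok], 150.0, None)
        main_sleep[manual] = np.clip(
            feats["total_sleep_time"][manual] + rng.normal(0.0, 30.0, int(manual.sum())),
            60.0,
            None,
        )
        main_sleep[short] = rng.uniform(30.0, 115.0, int(short.sum()))
        # A short manual entry stays short: the truncated duration wins.
        both = manual & short
        main_sleep[both] = rng.uniform(30.0, 115.0, int(both.sum()))

        mcar = rng.random((days, len(TIME_VARYING_FEATURES))) < MCAR_EXTRA_MISSING
        for k, f in enumerate(TIME_VARYING_FEATURES):
            observed = ~mcar[:, k]
            if f in SLEEP_FEATURES:
                observed &= night_ok
            else:
                observed &= wear_fraction >= 0.30
            feats[f] = np.where(observed, feats[f], np.nan)

        daily_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "day_index": np.arange(days),
                    "wear_fraction": wear_fraction,
                    **{f: feats[f] for f in TIME_VARYING_FEATURES},
                    "sleep_manual_flag": manual,
                    "main_sleep_duration": main_sleep,
                }
            )
        )

        # --- surveys --------------------------------------------------------
        survey_days = [0] + [
            d for d in followup_days if rng.random() < config.survey_response_prob
        ]
        for d in survey_days:
            latent = (
                ITEM_INTERCEPT
                + ITEM_GAMMA * severity[d]
                + rng.normal(0.0, ITEM_NOISE_SD, 14)
            )
            items = np.clip(np.round(latent), 1, 7).astype(int)
            pf, cw, ee, overall = score_smbm(items, config.smbm_map)
            assess_rows.append(
                {
                    "participant_id": pid,
                    "day_index": d,
                    **{f"item_{k + 1:02d}": int(items[k]) for k in range(14)},
                    "pf_score": pf,
                    "cw_score": cw,
                    "ee_score": ee,
                    "overall_score": overall,
                    "is_baseline": d == 0,
                }
            )

    daily = pd.concat(daily_rows, ignore_index=True)
    assessments = pd.DataFrame(assess_rows)
    return profiles, daily, assessments
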