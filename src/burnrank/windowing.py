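"""Pre-assessment window extraction.

Daily adherence rules: a *day* is adherent when the device was worn for at
least 70% of it; a *night* is adherent when a non-manually-reported primary
sleep session of at least two hours is present.  Each non-baseline survey
is mapped to the span of days immediately preceding it — up to 30 days,
shortened when the previous submission was more recent so that windows of
one participant never overlap — and kept only if it is at least 20 days
long and contains at least 10 adherent days and 10 adherent nights.
Participants contributing fewer than 14 cumulative adherent days are
excluded outright.
"""

from __future__ import annotations

from typing import Iterable, Set

import numpy as np
import pandas as pd

from .config import WindowConfig


def flag_adherence(daily: pd.DataFrame, config: WindowConfig | None = None) -> pd.DataFrame:
    """Compute per-day adherence flags from the daily table.

    Returns a frame with ``participant_id, day_index, day_adherent,
    night_adherent``; thresholds are inclusive (wear fraction exactly 0.70
    and a 120-minute session both count).
    """
    config = config or WindowConfig()
    required = {"participant_id", "day_index", "wear_fraction",
                "sleep_manual_flag", "main_sleep_duration"}
    missing = required - set(daily.columns)
    if missing:
        raise ValueError(f"daily table missing columns: {sorted(missing)}")
    wf = daily["wear_fraction"].to_numpy(dtype=float)
    if np.any((wf < 0) | (wf > 1)):
        raise ValueError("wear_fraction values must lie in [0, 1]")
    dur = daily["main_sleep_duration"].to_numpy(dtype=float)
    manual = daily["sleep_manual_flag"].to_numpy(dtype=bool)
    return pd.DataFrame(
        {
            "participant_id": daily["participant_id"].to_numpy(),
            "day_index": daily["day_index"].to_numpy(),
            "day_adherent": wf >= config.wear_threshold,
            "night_adherent": (
                np.isfinite(dur) & ~manual & (dur >= config.min_sleep_minutes)
            ),
        }
    )


def exclude_low_contribution(
    flags: pd.DataFrame, min_cumulative_days: int = 14
) -> Set:
    """Participants with at least `min_cumulative_days` adherent days."""
    if len(flags) == 0:
        return set()
    counts = flags.groupby("participant_id")["day_adherent"].sum()
    return set(counts[counts >= min_cumulative_days].index)


def extract_windows(
    assessments: pd.DataFrame,
    flags: pd.DataFrame,
    config: WindowConfig | None = None,
    participants: Iterable | None = None,
) -> pd.DataFrame:
    """Extract non-overlapping pre-assessment analysis windows.

    For each non-baseline assessment of each (retained) participant the
    candidate length is ``min(max_length, days since the previous
    submission)``, additionally capped by the study start; the window spans
    that many days ending the day before the assessment.  It is emitted only
    if it meets the length and adherence minima.  Baseline assessments never
    produce windows but anchor the first gap.

    By default every retained submission resets the gap anchor whether or
    not it yielded a valid window; set
    ``config.anchor_on_valid_windows_only`` for the alternative reading.
    """
    config = config or WindowConfig()
    if participants is not None:
        keep = set(participants)
        assessments = assessments[assessments["participant_id"].isin(keep)]
        flags = flags[flags["participant_id"].isin(keep)]

    flag_day = {}
    flag_night = {}
    for pid, grp in flags.groupby("participant_id"):
        idx = grp["day_index"].to_numpy()
        n = idx.max() + 1 if len(idx) else 0
        d = np.zeros(n, dtype=bool)
        nt = np.zeros(n, dtype=bool)
        d[idx] = grp["day_adherent"].to_numpy()
        nt[idx] = grp["night_adherent"].to_numpy()
        flag_day[pid] = d
        flag_night[pid] = nt

    rows = []
    for pid, grp in assessments.groupby("participant_id", sort=True):
        days = grp["day_index"].to_numpy()
        if np.any(np.diff(days) <= 0):
            raise ValueError(
                f"assessments of participant {pid!r} are not sorted by day"
            )
        d_adh = flag_day.get(pid, np.zeros(0, dtype=bool))
        n_adh = flag_night.get(pid, np.zeros(0, dtype=bool))
        anchor = None  # day of the previous anchoring submission
        for _, rec in grp.iterrows():
            day = int(rec["day_index"])
            if bool(rec["is_baseline"]):
                anchor = day
                continue
            gap = day - anchor if anchor is not None else day
            length = min(config.max_length, gap, day)
            emitted = False
            if length >= config.min_length:
                start, end = day - length, day - 1
                span = slice(start, end + 1)
                nd = int(d_adh[span].sum()) if end < len(d_adh) else int(
                    d_adh[start:].sum()
                )
                nn = int(n_adh[span].sum()) if end < len(n_adh) else int(
                    n_adh[start:].sum()
                )
                if nd >= config.min_adherent_days and nn >= config.min_adherent_nights:
                    rows.append(
                        {
                            "window_id": f"{pid}_d{day:03d}",
                            "participant_id": pid,
                            "assessment_day": day,
                            "start_day": start,
                            "end_day": end,
                            "length_days": length,
                            "n_adherent_days": nd,
                            "n_adherent_nights": nn,
                            "target_pf": float(rec["pf_score"]),
                            "target_cw": float(rec["cw_score"]),
                            "target_ee": float(rec["ee_score"]),
                            "target_overall": float(rec["overall_score"]),
                        }
                    )
                    emitted = True
            if emitted or not config.anchor_on_valid_windows_only:
                anchor = day
    columns = [
        "window_id", "participant_id", "assessment_day", "start_day", "end_day",
        "length_days", "n_adherent_days", "n_adherent_nights",
        "target_pf", "target_cw", "target_ee", "target_overall",
    ]
    return pd.DataFrame(rows, columns=columns)
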