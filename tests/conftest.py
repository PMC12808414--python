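import numpy as np
import pandas as pd
import pytest

from burnrank.config import CohortConfig, TIME_VARYING_FEATURES
from burnrank.cohort import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """50 participants, 9 months, moderate physiology-survey coupling."""
    cfg = CohortConfig(n_participants=50, latent_coupling=0.6, seed=11)
    return cfg, generate_cohort(cfg)


def make_daily(pid, days, wear=1.0, sleep_min=450.0, manual=False, features=None):
    """Hand-built daily rows with full feature coverage unless overridden."""
    n = len(days)
    base = {f: np.full(n, 50.0) for f in TIME_VARYING_FEATURES}
    if features:
        base.update(features)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "day_index": list(days),
            "wear_fraction": np.broadcast_to(wear, n).astype(float),
            **base,
            "sleep_manual_flag": np.broadcast_to(manual, n).astype(bool),
            "main_sleep_duration": np.broadcast_to(sleep_min, n).astype(float),
        }
    )


def make_assessments(pid, days, scores=None, baseline_first=True):
    rows = []
    for k, d in enumerate(days):
        s = scores[k] if scores is not None else 4.0
        rows.append(
            {
                "participant_id": pid,
                "day_index": d,
                **{f"item_{i:02d}": 4 for i in range(1, 15)},
                "pf_score": s,
                "cw_score": s,
                "ee_score": s,
                "overall_score": s,
                "is_baseline": baseline_first and k == 0,
            }
        )
    return pd.DataFrame(rows)
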