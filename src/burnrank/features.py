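"""Window-level feature engineering.

Two representations are built from the daily rows inside each analysis
window:

* an *aggregate* row per window — seven summary statistics (mean, sd, 25th
  and 75th percentile, skewness, excess kurtosis, zero-crossings of the
  mean-centered series) per time-varying feature, computed over observed
  values only, plus the eight time-invariant covariates;
* a *sequence* sample per window — the day × feature matrix after
  within-window median imputation, tail-padded to the maximum window
  length with an explicit validity length that downstream models must
  consume.

Also provides the one-way random-effects intraclass correlation (ICC)
used to characterize between- vs. within-person variance, and recursive
feature elimination down to a fixed number of aggregate columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression, Ridge

from .config import TIME_INVARIANT_COVARIATES, TIME_VARYING_FEATURES

logger = logging.getLogger(__name__)

AGGREGATE_STATS = ("mean", "sd", "p25", "p75", "skewness", "kurtosis", "zero_crossings")

#: Continuous covariates standardized with training-fold statistics;
#: binary covariates pass through as 0/1.
CONTINUOUS_COVARIATES = ("age", "bmi")


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute_window_median(
    values: np.ndarray,
    participant_medians: Optional[np.ndarray] = None,
    cohort_medians: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Replace missing cells by the within-window median of their feature.

    ``values`` is a (days, features) array with NaN marking missingness.
    A feature fully missing inside the window falls back to the
    participant-level median, then the cohort median (both optional,
    logged when used); a cell with no fallback at all raises.
    Observed cells are never altered.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a (days, features) matrix")
    out = values.copy()
    for f in range(values.shape[1]):
        col = out[:, f]
        mask = np.isnan(col)
        if not mask.any():
            continue
        observed = col[~mask]
        if len(observed):
            fill = float(np.median(observed))
        elif participant_medians is not None and np.isfinite(participant_medians[f]):
            fill = float(participant_medians[f])
            logger.info("feature %d fully missing in window; participant median used", f)
        elif cohort_medians is not None and np.isfinite(cohort_medians[f]):
            fill = float(cohort_medians[f])
            logger.info("feature %d fully missing in window; cohort median used", f)
        else:
            raise ValueError(f"feature column {f} has no observed values anywhere")
        col[mask] = fill
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def zero_crossings(series: np.ndarray) -> int:
    """Sign changes of the mean-centered series, in temporal order.

    Exact zeros inherit the previous sign, so touching the mean without
    crossing it does not count.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return 0
    centered = x - x.mean()
    signs = np.sign(centered)
    count = 0
    prev = 0.0
    for s in signs:
        if s == 0.0:
            continue
        if prev != 0.0 and s != prev:
            count += 1
        prev = s
    return count


def aggregate_series(series: np.ndarray) -> Dict[str, float]:
    """The seven summary statistics over the observed values of one feature."""
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return {s: np.nan for s in AGGREGATE_STATS}
    out: Dict[str, float] = {
        "mean": float(x.mean()),
        "p25": float(np.quantile(x, 0.25)),  # linear-interpolation quantiles
        "p75": float(np.quantile(x, 0.75)),
        "zero_crossings": float(zero_crossings(x)),
    }
    if len(x) >= 2:
        out["sd"] = float(x.std(ddof=1))
        # Adjusted (sample) skewness and excess kurtosis; NaN on constants.
        if out["sd"] > 0 and len(x) >= 3:
            out["skewness"] = float(stats.skew(x, bias=False))
        else:
            out["skewness"] = np.nan
        if out["sd"] > 0 and len(x) >= 4:
            out["kurtosis"] = float(stats.kurtosis(x, bias=False))
        else:
            out["kurtosis"] = np.nan
    else:
        logger.info("fewer than 2 observed values; sd/skewness/kurtosis null")
        out["sd"] = np.nan
        out["skewness"] = np.nan
        out["kurtosis"] = np.nan
    return out


def aggregate_window(values: np.ndarray, feature_names: Sequence[str] = TIME_VARYING_FEATURES) -> Dict[str, float]:
    """Aggregate one window's raw (non-imputed) day × feature matrix."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty window")
    row: Dict[str, float] = {}
    for k, name in enumerate(feature_names):
        for stat, v in aggregate_series(values[:, k]).items():
            row[f"{name}_{stat}"] = v
    return row


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def compute_icc(values: Sequence[float], groups: Sequence) -> float:
    """One-way random-effects ICC(1) from ANOVA mean squares.

    Uses the unbalanced-design group-size correction
    ``n0 = (N - sum(n_i^2)/N) / (k - 1)`` and clips negative estimates to 0.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    df = df.dropna()
    sizes = df.groupby("group").size()
    k = len(sizes)
    if k < 2:
        raise ValueError("ICC requires at least two participants")
    if (sizes < 2).all():
        raise ValueError("ICC requires repeated observations for at least one participant")
    N = len(df)
    grand = df["value"].mean()
    means = df.groupby("group")["value"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["value"] - means.loc[df["group"]].to_numpy()) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    icc = (msb - msw) / (msb + (n0 - 1) * msw)
    return float(min(max(icc, 0.0), 1.0))


def icc_report(daily: pd.DataFrame, features: Sequence[str] = TIME_VARYING_FEATURES) -> Dict[str, float]:
    return {
        f: compute_icc(daily[f].to_numpy(), daily["participant_id"].to_numpy())
        for f in features
    }


# ---------------------------------------------------------------------------
# Aggregate table and sequence tensors
# ---------------------------------------------------------------------------

def build_aggregate_table(
    windows: pd.DataFrame, daily: pd.DataFrame, profiles: pd.DataFrame
) -> pd.DataFrame:
    """One aggregate-feature row per analysis window (57 design columns)."""
    daily_by_pid = {pid: grp.set_index("day_index") for pid, grp in daily.groupby("participant_id")}
    prof = profiles.set_index("participant_id")
    rows = []
    for _, w in windows.iterrows():
        grp = daily_by_pid[w["participant_id"]]
        span = grp.loc[w["start_day"] : w["end_day"], list(TIME_VARYING_FEATURES)]
        row = {"window_id": w["window_id"], "participant_id": w["participant_id"]}
        row.update(aggregate_window(span.to_numpy()))
        for cov in TIME_INVARIANT_COVARIATES:
            row[cov] = float(prof.at[w["participant_id"], cov])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SequenceDataset:
    """Padded sequence tensors for the recurrent models.

    ``X`` is (n_windows, max_len, n_features) with tail padding (zeros after
    scaling); rows at or beyond ``lengths[i]`` are padding and must never
    influence model output.  Targets are carried per component.
    """

    window_ids: np.ndarray
    participants: np.ndarray
    X: np.ndarray
    lengths: np.ndarray
    Z: np.ndarray
    targets: Dict[str, np.ndarray]

    def __len__(self) -> int:
        return len(self.window_ids)


def build_sequences(
    windows: pd.DataFrame,
    daily: pd.DataFrame,
    profiles: pd.DataFrame,
    max_len: int = 30,
) -> SequenceDataset:
    """Assemble imputed, tail-padded sequence samples for every window."""
    daily_by_pid = {pid: grp.set_index("day_index") for pid, grp in daily.groupby("participant_id")}
    cohort_medians = daily[list(TIME_VARYING_FEATURES)].median().to_numpy()
    prof = profiles.set_index("participant_id")
    n = len(windows)
    nf = len(TIME_VARYING_FEATURES)
    X = np.zeros((n, max_len, nf))
    lengths = np.zeros(n, dtype=int)
    Z = np.zeros((n, len(TIME_INVARIANT_COVARIATES)))
    for r, (_, w) in enumerate(windows.iterrows()):
        pid = w["participant_id"]
        grp = daily_by_pid[pid]
        span = grp.loc[w["start_day"] : w["end_day"], list(TIME_VARYING_FEATURES)].to_numpy()
        part_medians = grp[list(TIME_VARYING_FEATURES)].median().to_numpy()
        imputed = impute_window_median(span, part_medians, cohort_medians)
        L = imputed.shape[0]
        if L > max_len:
            raise ValueError(f"window longer than max_len={max_len}")
        X[r, :L, :] = imputed
        lengths[r] = L
        Z[r] = [float(prof.at[pid, c]) for c in TIME_INVARIANT_COVARIATES]
    targets = {
        comp: windows[f"target_{comp}"].to_numpy(dtype=float)
        for comp in ("pf", "cw", "ee", "overall")
    }
    return SequenceDataset(
        window_ids=windows["window_id"].to_numpy(),
        participants=windows["participant_id"].to_numpy(),
        X=X,
        lengths=lengths,
        Z=Z,
        targets=targets,
    )


class FoldScaler:
    """Standardization fitted on training-fold data only.

    Sequence features are z-scored per feature over observed (non-padded)
    time steps; continuous covariates are z-scored, binary covariates pass
    through.  Padded tails are re-zeroed after scaling so padding stays
    inert.
    """

    def fit(self, X: np.ndarray, lengths: np.ndarray, Z: np.ndarray) -> "FoldScaler":
        mask = np.arange(X.shape[1])[None, :] < lengths[:, None]
        flat = X[mask]  # (total_days, n_features)
        self.x_mean = flat.mean(axis=0)
        self.x_std = np.where(flat.std(axis=0) > 0, flat.std(axis=0), 1.0)
        self.z_mean = np.zeros(Z.shape[1])
        self.z_std = np.ones(Z.shape[1])
        for k, cov in enumerate(TIME_INVARIANT_COVARIATES):
            if cov in CONTINUOUS_COVARIATES:
                self.z_mean[k] = Z[:, k].mean()
                s = Z[:, k].std()
                self.z_std[k] = s if s > 0 else 1.0
        return self

    def transform(self, X: np.ndarray, lengths: np.ndarray, Z: np.ndarray):
        Xs = (X - self.x_mean) / self.x_std
        mask = np.arange(X.shape[1])[None, :] < lengths[:, None]
        Xs[~mask] = 0.0
        Zs = (Z - self.z_mean) / self.z_std
        return Xs, Zs


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 15,
    task: str = "regress",
    estimator=None,
    step: int = 1,
) -> np.ndarray:
    """Recursive feature elimination down to exactly ``k`` columns.

    Must be fitted on training-fold rows only; returns a boolean mask over
    the columns of ``X``.  The base estimator defaults to ridge regression
    (continuous targets) or L2 logistic regression (binary targets).
    """
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available columns")
    if k == X.shape[1]:
        return np.ones(X.shape[1], dtype=bool)
    if estimator is None:
        estimator = (
            Ridge(alpha=1.0)
            if task == "regress"
            else LogisticRegression(max_iter=1000)
        )
    values = X.to_numpy(dtype=float)
    # RFE cannot rank columns through NaNs; fill with column medians.
    col_med = np.nanmedian(values, axis=0)
    col_med = np.where(np.isfinite(col_med), col_med, 0.0)
    values = np.where(np.isfinite(values), values, col_med)
    mu, sd = values.mean(axis=0), values.std(axis=0)
    values = (values - mu) / np.where(sd > 0, sd, 1.0)
    rfe = RFE(estimator, n_features_to_select=k, step=step)
    rfe.fit(values, np.asarray(y))
    return rfe.support_
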