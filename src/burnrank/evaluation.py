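"""Cross-validated evaluation: folds, metrics, reference baselines, tests.

Evaluation follows a stratified subject-wise design: participants (never
windows) are dealt into folds, stratified by quartile bins of their mean
target score, so no participant's windows straddle a train/test boundary.
Results are aggregated over folds x seeds and reported as
median (p25-p75), with one-sided Wilcoxon signed-rank tests against the
relevant reference baseline at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import f1_score, roc_auc_score

from .config import EncoderConfig, TrainConfig, WindowConfig
from .features import (
    FoldScaler,
    SequenceDataset,
    build_aggregate_table,
    build_sequences,
    select_features,
)
from .models import dichotomize, fit_tabular_baselines
from .nn.gru import InvariantScorer
from .nn.training import train_pointwise, train_siamese
from .windowing import exclude_low_contribution, extract_windows, flag_adherence

ALPHA = 0.05


# ---------------------------------------------------------------------------
# CV plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    n_folds: int
    fold_of: Dict[object, int]
    strat_bin: Dict[object, int]
    seed: int

    def test_participants(self, fold: int) -> List:
        return [p for p, f in self.fold_of.items() if f == fold]


def build_cv_plan(
    participants: Sequence,
    targets: Sequence[float],
    n_folds: int = 10,
    seed: int = 0,
) -> CVPlan:
    """Deal participants into stratified subject-wise folds.

    The stratification value for a participant is the mean of their window
    targets, binned into quartiles; bins are dealt round-robin after a
    seeded shuffle, so folds are balanced across the target distribution.
    """
    df = pd.DataFrame({"pid": list(participants), "t": np.asarray(targets, float)})
    subj = df.groupby("pid")["t"].mean()
    if len(subj) < n_folds:
        raise ValueError(f"{len(subj)} participants cannot fill {n_folds} folds")
    try:
        bins = pd.qcut(subj, 4, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=subj.index)
    bins = bins.fillna(0).astype(int)
    rng = np.random.default_rng(seed)
    fold_of: Dict[object, int] = {}
    counter = 0
    for b in sorted(bins.unique()):
        pids = np.array(sorted(bins[bins == b].index))
        rng.shuffle(pids)
        for pid in pids:
            fold_of[pid] = counter % n_folds
            counter += 1
    return CVPlan(n_folds, fold_of, {p: int(bins[p]) for p in subj.index}, seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def ndcg(predicted: Sequence[float], relevance: Sequence[float], ids: Optional[Sequence] = None) -> float:
    """Normalized discounted cumulative gain with exponential gains.

    Items are sorted by predicted score descending (stable tie-break by
    item id); DCG = sum over ranks i (1-based) of (2^rel_i - 1)/log2(i+1),
    normalized by the DCG of the ideal (relevance-sorted) ordering.  A list
    whose relevances are all zero has ideal DCG 0 and is defined as 1.
    """
    predicted = np.asarray(predicted, dtype=float)
    relevance = np.asarray(relevance, dtype=float)
    if len(predicted) == 0:
        raise ValueError("ndcg of an empty list is undefined")
    if len(predicted) != len(relevance):
        raise ValueError("predicted and relevance lengths differ")
    if np.any(relevance < 0):
        raise ValueError("relevance values must be nonnegative")
    ids = np.asarray(ids if ids is not None else np.arange(len(predicted)))
    order = np.lexsort((ids, -predicted))  # score desc, id asc on ties
    discounts = 1.0 / np.log2(np.arange(2, len(predicted) + 2))
    gains = 2.0**relevance - 1.0
    dcg = float((gains[order] * discounts).sum())
    ideal = float((np.sort(gains)[::-1] * discounts).sum())
    if ideal == 0.0:
        return 1.0
    return dcg / ideal


def spearman_rho(predicted: Sequence[float], target: Sequence[float]) -> float:
    """Spearman rank correlation with midrank ties; NaN on zero variance."""
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(predicted) < 2:
        raise ValueError("spearman requires at least two observations")
    if (
        not (np.isfinite(predicted).all() and np.isfinite(target).all())
        or predicted.max() == predicted.min()
        or target.max() == target.min()
    ):
        return float("nan")
    return float(sps.spearmanr(predicted, target).statistic)


def classification_metrics(probabilities: Sequence[float], labels: Sequence[int]) -> Tuple[float, float]:
    """(ROC-AUC, F1 of the high-risk class at probability threshold 0.5).

    AUC is reported as NaN when the test labels are single-class.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) != len(y):
        raise ValueError("probabilities and labels lengths differ")
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan")
    f1 = float(f1_score(y, (p >= 0.5).astype(int), pos_label=1, zero_division=0.0))
    return auc, f1


# ---------------------------------------------------------------------------
# Reference baselines
# ---------------------------------------------------------------------------

def baseline_brg(train_labels: Sequence[int], size: int, seed: int = 0) -> np.ndarray:
    """Biased random guesser: i.i.d. draws from the empirical label mix."""
    y = np.asarray(train_labels, dtype=int)
    if len(y) == 0:
        raise ValueError("BRG needs a nonempty training label set")
    p_high = y.mean()
    rng = np.random.default_rng(seed)
    return (rng.random(size) < p_high).astype(float)


def baseline_naive_mean(train_targets: Sequence[float]):
    """Constant predictor of the training-set mean."""
    mean = float(np.mean(np.asarray(train_targets, dtype=float)))

    def predict(n: int) -> np.ndarray:
        return np.full(n, mean)

    return predict


def baseline_random_ranker(
    relevance: Sequence[float], n_draws: int = 1000, seed: int = 0
) -> float:
    """Mean NDCG of uniformly random orderings of the test items."""
    relevance = np.asarray(relevance, dtype=float)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_draws):
        scores = rng.permutation(len(relevance)).astype(float)
        vals.append(ndcg(scores, relevance))
    return float(np.mean(vals))


def train_invariant_ranker(
    Z: np.ndarray,
    targets: np.ndarray,
    participants: np.ndarray,
    encoder_cfg: EncoderConfig,
    train_cfg: TrainConfig,
):
    """Pairwise-trained feed-forward ranker on time-invariant covariates only."""
    n = len(targets)
    dummy_X = np.zeros((n, 1, 1))
    dummy_len = np.ones(n, dtype=int)
    model = InvariantScorer(Z.shape[1], encoder_cfg)
    return train_siamese(
        dummy_X, dummy_len, Z, targets, participants, encoder_cfg, train_cfg, model=model
    )


# ---------------------------------------------------------------------------
# Significance
# ---------------------------------------------------------------------------

@dataclass
class SignificanceResult:
    label: str
    statistic: float
    p_value: float
    significant: bool


def compare_wilcoxon(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "greater",
    label: str = "",
) -> SignificanceResult:
    """Paired one-sided Wilcoxon signed-rank test at alpha = 0.05.

    NaN pairs are dropped; an all-zero difference vector (or fewer than two
    usable pairs) is reported as non-significant with p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length vectors")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    d = a - b
    if len(d) < 2 or np.all(d == 0):
        return SignificanceResult(label, float("nan"), 1.0, False)
    res = sps.wilcoxon(a, b, alternative=alternative)
    return SignificanceResult(
        label, float(res.statistic), float(res.pvalue), bool(res.pvalue < ALPHA)
    )


def summarize(values: Iterable[float]) -> Dict[str, float]:
    """Median (p25-p75) over fold x seed values, ignoring NaNs."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return {"median": float("nan"), "p25": float("nan"), "p75": float("nan")}
    return {
        "median": float(np.median(v)),
        "p25": float(np.quantile(v, 0.25)),
        "p75": float(np.quantile(v, 0.75)),
    }


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------

RANK_MODELS = ("sgru_mrl", "sgru_bce", "gru_pointwise", "invariant")
CLASSIFY_MODELS = ("brg", "logreg", "lda", "qda", "rf", "gru")
REGRESS_MODELS = ("naive", "lasso", "ridge", "elasticnet", "rf", "gru")


@dataclass
class ExperimentReport:
    task: str
    component: str
    per_fold: Dict[str, Dict[str, List[float]]]
    summary: Dict[str, Dict[str, Dict[str, float]]]
    significance: Dict[str, SignificanceResult]
    n_windows: int
    n_participants: int
    meta: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "component": self.component,
            "n_windows": self.n_windows,
            "n_participants": self.n_participants,
            "per_fold": self.per_fold,
            "summary": self.summary,
            "significance": {
                k: {
                    "statistic": v.statistic,
                    "p_value": v.p_value,
                    "significant": v.significant,
                }
                for k, v in self.significance.items()
            },
            "meta": self.meta,
        }


def _stage_seed(base: int, fold: int, tag: int) -> int:
    return (base * 1009 + fold * 97 + tag) % (2**31 - 1)


def prepare_windows(
    profiles: pd.DataFrame,
    daily: pd.DataFrame,
    assessments: pd.DataFrame,
    window_cfg: Optional[WindowConfig] = None,
) -> Tuple[pd.DataFrame, SequenceDataset]:
    """Adherence flags -> participant exclusion -> windows -> sequences."""
    window_cfg = window_cfg or WindowConfig()
    flags = flag_adherence(daily, window_cfg)
    retained = exclude_low_contribution(flags, window_cfg.min_cumulative_days)
    windows = extract_windows(assessments, flags, window_cfg, participants=retained)
    if len(windows) == 0:
        raise ValueError("no valid analysis windows extracted")
    dataset = build_sequences(windows, daily, profiles, max_len=window_cfg.max_length)
    return windows, dataset


def run_experiment(
    profiles: pd.DataFrame,
    daily: pd.DataFrame,
    assessments: pd.DataFrame,
    task: str = "rank",
    component: str = "pf",
    models: Optional[Sequence[str]] = None,
    n_folds: int = 10,
    seeds: Sequence[int] = (0,),
    window_cfg: Optional[WindowConfig] = None,
    encoder_cfg: Optional[EncoderConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    n_random_rankings: int = 1000,
    k_features: int = 15,
    n_inner_folds: int = 3,
) -> ExperimentReport:
    """Nested subject-wise cross-validated evaluation of one component.

    Runs the requested model family over ``n_folds`` outer folds and the
    given seeds, computing per-fold test metrics, median (p25-p75)
    summaries, and Wilcoxon comparisons against the task's reference
    baseline (biased random guesser, naive mean, or random/invariant
    rankers).  Deterministic given the seed list.
    """
    if task not in ("rank", "classify", "regress"):
        raise ValueError(f"unknown task {task!r}")
    defaults = {"rank": RANK_MODELS, "classify": CLASSIFY_MODELS, "regress": REGRESS_MODELS}
    models = tuple(models) if models is not None else defaults[task]
    window_cfg = window_cfg or WindowConfig()
    encoder_cfg = encoder_cfg or EncoderConfig()
    train_cfg = train_cfg or TrainConfig()

    windows, dataset = prepare_windows(profiles, daily, assessments, window_cfg)
    targets = dataset.targets[component]
    participants = dataset.participants
    labels = dichotomize(targets, component) if task == "classify" else None

    need_tabular = any(
        m in ("logreg", "lda", "qda", "rf", "lasso", "ridge", "elasticnet") for m in models
    )
    agg = build_aggregate_table(windows, daily, profiles) if need_tabular else None
    if agg is not None:
        feature_cols = [c for c in agg.columns if c not in ("window_id", "participant_id")]

    per_fold: Dict[str, Dict[str, List[float]]] = {m: {} for m in models}
    per_fold["random"] = {}

    def record(model: str, metric: str, value: float) -> None:
        per_fold.setdefault(model, {}).setdefault(metric, []).append(float(value))

    for seed in seeds:
        plan = build_cv_plan(participants, targets, n_folds=n_folds, seed=seed)
        fold_ids = np.array([plan.fold_of[p] for p in participants])
        for fold in range(n_folds):
            test = fold_ids == fold
            train = ~test
            if test.sum() < 2 or train.sum() < 4:
                continue
            scaler = FoldScaler().fit(
                dataset.X[train], dataset.lengths[train], dataset.Z[train]
            )
            Xtr, Ztr = scaler.transform(
                dataset.X[train], dataset.lengths[train], dataset.Z[train]
            )
            Xte, Zte = scaler.transform(
                dataset.X[test], dataset.lengths[test], dataset.Z[test]
            )
            Ltr, Lte = dataset.lengths[train], dataset.lengths[test]
            ytr, yte = targets[train], targets[test]
            ptr = participants[train]
            rel_te = yte  # raw 1-7 scores as NDCG relevance

            if task == "rank":
                record(
                    "random",
                    "ndcg",
                    baseline_random_ranker(
                        rel_te, n_random_rankings, _stage_seed(seed, fold, 7)
                    ),
                )

            for model in models:
                tag = sum(model.encode()) % 89  # stable across processes
                mseed = _stage_seed(seed, fold, tag)
                enc = EncoderConfig(**{**encoder_cfg.__dict__, "seed": mseed})
                if task == "rank":
                    if model in ("sgru_mrl", "sgru_bce"):
                        tc = TrainConfig(
                            **{
                                **train_cfg.__dict__,
                                "loss": "rank_margin" if model == "sgru_mrl" else "rank_bce",
                                "seed": mseed,
                            }
                        )
                        scorer = train_siamese(Xtr, Ltr, Ztr, ytr, ptr, enc, tc)
                        preds = scorer.score(Xte, Lte, Zte)
                    elif model == "gru_pointwise":
                        tc = TrainConfig(
                            **{**train_cfg.__dict__, "loss": "mse_reg", "seed": mseed}
                        )
                        scorer = train_pointwise(Xtr, Ltr, Ztr, ytr, ptr, enc, tc)
                        preds = scorer.score(Xte, Lte, Zte)
                    elif model == "invariant":
                        tc = TrainConfig(
                            **{
                                **train_cfg.__dict__,
                                "loss": train_cfg.loss
                                if train_cfg.loss in ("rank_margin", "rank_bce")
                                else "rank_margin",
                                "seed": mseed,
                            }
                        )
                        scorer = train_invariant_ranker(Ztr, ytr, ptr, enc, tc)
                        preds = scorer.score(Xte, Lte, Zte)
                    else:
                        raise ValueError(f"unknown ranking model {model!r}")
                    record(model, "spearman", spearman_rho(preds, yte))
                    record(model, "ndcg", ndcg(preds, rel_te))

                elif task == "classify":
                    ltr, lte_b = labels[train], labels[test]
                    if model == "brg":
                        probs = baseline_brg(ltr, int(test.sum()), mseed)
                    elif model == "gru":
                        tc = TrainConfig(
                            **{**train_cfg.__dict__, "loss": "bce_class", "seed": mseed}
                        )
                        scorer = train_pointwise(
                            Xtr, Ltr, Ztr, ltr.astype(float), ptr, enc, tc
                        )
                        probs = scorer.predict_proba(Xte, Lte, Zte)
                    else:
                        sel = select_features(
                            agg.loc[train, feature_cols], ltr, k=k_features,
                            task="classify",
                        )
                        cols = list(np.array(feature_cols)[sel])
                        fitted = fit_tabular_baselines(
                            agg.loc[train, cols].to_numpy(), ltr, "classify",
                            groups=ptr, n_inner_folds=n_inner_folds, seed=mseed,
                            models=(model,),
                        )[model]
                        probs = fitted.predict_proba(agg.loc[test, cols].to_numpy())[:, 1]
                    auc, f1 = classification_metrics(probs, lte_b)
                    record(model, "roc_auc", auc)
                    record(model, "f1", f1)

                else:  # regress
                    if model == "naive":
                        preds = baseline_naive_mean(ytr)(int(test.sum()))
                    elif model == "gru":
                        tc = TrainConfig(
                            **{**train_cfg.__dict__, "loss": "mse_reg", "seed": mseed}
                        )
                        scorer = train_pointwise(Xtr, Ltr, Ztr, ytr, ptr, enc, tc)
                        preds = scorer.score(Xte, Lte, Zte)
                    else:
                        sel = select_features(
                            agg.loc[train, feature_cols], ytr, k=k_features,
                            task="regress",
                        )
                        cols = list(np.array(feature_cols)[sel])
                        fitted = fit_tabular_baselines(
                            agg.loc[train, cols].to_numpy(), ytr, "regress",
                            groups=ptr, n_inner_folds=n_inner_folds, seed=mseed,
                            models=(model,),
                        )[model]
                        preds = fitted.predict(agg.loc[test, cols].to_numpy())
                    record(model, "mae", float(np.mean(np.abs(preds - yte))))
                    record(model, "spearman", spearman_rho(preds, yte))

    summary = {
        m: {metric: summarize(vals) for metric, vals in metrics.items()}
        for m, metrics in per_fold.items()
    }

    significance: Dict[str, SignificanceResult] = {}
    if task == "rank":
        for m in models:
            if m == "invariant":
                continue
            significance[f"{m}_vs_random_ndcg"] = compare_wilcoxon(
                per_fold[m]["ndcg"], per_fold["random"]["ndcg"], "greater",
                f"{m}_vs_random_ndcg",
            )
            if "invariant" in per_fold:
                for metric in ("spearman", "ndcg"):
                    significance[f"{m}_vs_invariant_{metric}"] = compare_wilcoxon(
                        per_fold[m][metric], per_fold["invariant"][metric], "greater",
                        f"{m}_vs_invariant_{metric}",
                    )
    elif task == "classify":
        for m in models:
            if m == "brg":
                continue
            for metric in ("roc_auc", "f1"):
                significance[f"{m}_vs_brg_{metric}"] = compare_wilcoxon(
                    per_fold[m][metric], per_fold["brg"][metric], "greater",
                    f"{m}_vs_brg_{metric}",
                )
    else:
        for m in models:
            if m == "naive":
                continue
            significance[f"{m}_vs_naive_mae"] = compare_wilcoxon(
                per_fold["naive"]["mae"], per_fold[m]["mae"], "greater",
                f"{m}_vs_naive_mae",
            )
            vals = np.asarray(per_fold[m]["spearman"], dtype=float)
            significance[f"{m}_rho_gt_zero"] = compare_wilcoxon(
                vals, np.zeros_like(vals), "greater", f"{m}_rho_gt_zero"
            )

    return ExperimentReport(
        task=task,
        component=component,
        per_fold=per_fold,
        summary=summary,
        significance=significance,
        n_windows=len(windows),
        n_participants=len(set(participants)),
        meta={"n_folds": n_folds, "seeds": list(seeds)},
    )
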