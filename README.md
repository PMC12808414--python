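# burnrank

Unobtrusive burnout-risk prediction from wearable trajectories, framed as a
**learning-to-rank** problem.

Burnout severity is measured by the 14-item Shirom–Melamed Burnout Measure
(SMBM): 1–7 Likert items grouped into Physical Fatigue (PF), Cognitive
Weariness (CW) and Emotional Exhaustion (EE) subscales, each scored as the
mean of its items. Predicting these scores from passively collected wearable
data (sleep, heart rate, stress, activity) is hard in absolute terms, but
the *relative ordering* of individuals by risk carries recoverable signal.
`burnrank` implements the full pipeline for studying this:

- a **synthetic cohort simulator** with a latent severity process coupling
  daily physiology to monthly surveys at tunable strength, controllable
  between-/within-person variance (ICC targets), sparse survey completion
  and realistic day/night adherence gaps;
- **adherence-gated windowing**: 20–30-day non-overlapping spans preceding
  each survey, requiring ≥ 10 adherent days (≥ 70% wear) and ≥ 10 adherent
  nights (non-manual sleep session ≥ 2 h);
- **feature representations**: per-window summary statistics (mean, sd,
  quartiles, skewness, kurtosis, zero-crossings) over observed values for
  tabular models, and median-imputed padded day × feature sequences for
  recurrent models;
- **models**: scikit-learn classification/regression baselines, a pointwise
  GRU, and a **siamese GRU ranker** trained on window pairs whose target
  scores differ by ≥ 0.5, with either the margin ranking loss
  `max(0, −y·(ŷᵢ − ŷⱼ) + ε)` (ε = 0.5) or RankNet-style BCE on
  `σ(ŷᵢ − ŷⱼ)`; all neural code runs on a small numpy autodiff engine;
- **evaluation**: stratified subject-wise 10-fold cross-validation,
  Spearman ρ, NDCG (`DCG = Σ (2^relᵢ − 1)/log₂(i+1)`, normalized by the
  ideal ordering), ROC-AUC/F1, reference baselines (biased random guesser,
  naive mean, random ranker, time-invariant ranker) and one-sided Wilcoxon
  signed-rank comparisons.

## Worked example

```python
from burnrank import CohortConfig, generate_cohort, run_experiment
from burnrank.config import EncoderConfig, TrainConfig

cfg = CohortConfig(n_participants=60, study_days=180, latent_coupling=0.6, seed=7)
profiles, daily, assessments = generate_cohort(cfg)

report = run_experiment(
    profiles, daily, assessments,
    task="rank", component="pf", models=("sgru_mrl", "invariant"),
    n_folds=5, seeds=(0,),
    encoder_cfg=EncoderConfig(hidden_size=8, head_hidden_size=8, dropout=0.1),
    train_cfg=TrainConfig(learning_rate=1e-3, max_epochs=10, patience=5,
                          max_pairs_per_epoch=1024),
    n_random_rankings=200,
)
print(report.n_windows, report.n_participants)
print(report.summary["sgru_mrl"]["spearman"])
print(report.summary["random"]["ndcg"])
print(report.significance["sgru_mrl_vs_invariant_spearman"].p_value)
```

prints

```
85 46
{'median': 0.6159000424254666, 'p25': 0.5379739984173496, 'p75': 0.6716061363196815}
{'median': 0.6668639853977233, 'p25': 0.6485773727328404, 'p75': 0.7236799679358848}
0.03125
```

85 analysis windows from 46 retained participants; the siamese margin-loss
ranker reaches a median test Spearman ρ of 0.62 against the PF subscale
(random ordering would center on 0; the planted coupling of 0.6 is strong at
this cohort size), the random ranker's NDCG centers near 0.67, and the
siamese model beats the ranker that only sees demographic/occupational
covariates (one-sided Wilcoxon p = 0.031, the smallest attainable over 5
folds).

The same pipeline is scriptable from the shell:

```bash
burnrank simulate --seed 7 --out cohort/
burnrank extract-windows --cohort cohort/ --out windows.csv
burnrank featurize --cohort cohort/ --windows windows.csv --out features/
burnrank evaluate --cohort cohort/ --task rank --component pf --out report.json
burnrank report --report report.json
```

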