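# Methods

## Problem and scope

`burnrank` predicts *relative* burnout risk from passively collected wearable
data. Burnout severity is measured by the 14-item Shirom–Melamed Burnout
Measure (SMBM): each item is answered on a 1–7 Likert scale, subscale scores
(Physical Fatigue, PF; Cognitive Weariness, CW; Emotional Exhaustion, EE) are
the means of their items, and the overall score is the item-count-weighted
average of the subscales — equivalently the mean of all 14 items. The package
implements the full prediction pipeline: a synthetic cohort simulator,
adherence-gated pre-assessment windowing, aggregate and sequential feature
representations, tabular classification/regression baselines, a siamese
recurrent pairwise ranker, and subject-wise cross-validated evaluation with
ranking metrics. Because the motivating real-world cohort data are available
only on request, the simulator is the package's first-class data source and
all experiments are run end to end on it.

## Synthetic cohort model

Each participant carries a latent severity process

    s_it = b_i + w_it,

with stable trait `b_i ~ N(0, σ_b²)` (σ_b = 1) and a stationary
mean-reverting Gaussian walk `w_it` (AR(1), day-to-day autocorrelation 0.98,
marginal sd σ_w = 0.65). The mean-reverting form keeps severity bounded in
distribution and — because it is stationary — makes the between/within
variance budget analytically calibratable. The calibration (σ_b, σ_w, item
loading γ = 1.1, item noise sd 0.8) was chosen so the simulated subscale
scores have mean ≈ 3.3, sd ≈ 1.2 and a subject-level ICC near 0.7, i.e. the
high temporal stability reported for this instrument.

Survey items discretize `3.2 + γ·s_it + noise` onto 1..7; the default item →
subscale partition is the standard 6 PF / 5 CW / 3 EE split (configurable,
since alternative orderings of the questionnaire exist). Surveys are
scheduled every `survey_interval_days` (day 0 is an always-completed baseline
that is never windowed); follow-ups are completed with probability 0.28,
matching sparse real-world completion.

Daily features are built on a standardized latent scale,

    z_ift = u_if + c·β_f·s_it + e_ift,

where `c = latent_coupling` and β_f = ±0.35 with physiologically sensible
signs (higher severity → shorter, lighter sleep; higher heart rates; more
stress; more sedentary time). The variances of the subject effect `u` and
the daily noise `e` are solved so that the between/(between+within) ratio
equals `icc_targets[f]` *including* the severity contribution; consequently
ICC targets are hit for any coupling, and at `c = 0` physiology is exactly
independent of the surveys. Defaults give cardiac features higher ICC
(0.60–0.65) than sleep/stress/activity features (0.30–0.45), mirroring the
reported pattern. Latent scales map to natural units via fixed
location/scale pairs (e.g. total sleep time 420 ± 50 min, rest HR 56 ± 6
bpm); bounded quantities are clipped to their domains.

Missingness is completely at random by default: days are non-adherent
(wear fraction < 0.70) with probability `1 − wear_adherence_rate` (default
0.664, the reported daily adherence), and nightly sleep sessions are absent,
manually entered, or truncated below two hours at rates solved so the
realized adherent-night fraction equals `night_adherence_rate` (default
0.827). Sleep-derived features are observed only on adherent-quality nights;
daytime features require a minimally worn device; 2% extra cells are dropped
at random. An optional severity-linked missingness mode (logistic shift of
adherence by severity, off by default) exists because real missingness may
correlate with the very states being predicted. What the simulator does
*not* emulate: minute-level signals, device-specific stress algorithms,
seasonal/weekday structure, covariate–severity confounding (demographics are
independent of severity unless planted), and informative missingness by
default — so green tests show pipeline correctness and recoverability of a
planted signal, not real-world effect sizes.

## Windowing

A day is adherent at wear fraction ≥ 0.70; a night is adherent when a
non-manually-reported primary sleep session ≥ 120 min is present (both
boundaries inclusive). Participants with fewer than 14 cumulative adherent
days are excluded. Each non-baseline survey maps to the span of up to 30
days ending the day before submission, shortened to the gap since the
previous submission; windows shorter than 20 days, or with fewer than 10
adherent days or 10 adherent nights, are dropped. Windows of one participant
are disjoint by construction. Day indexing is 0-based and window endpoints
are inclusive. By default every retained submission resets the gap anchor
whether or not it produced a valid window ("no temporal overlap" is about
submissions); `anchor_on_valid_windows_only` flips to the other reading.

## Features

Aggregate rows hold seven statistics per time-varying feature — mean, sd
(ddof 1), 25th/75th percentile (type-7 linear interpolation), adjusted
sample skewness, adjusted excess kurtosis, and zero-crossings — computed
over *observed* values only, plus the eight time-invariant covariates
(gender, age, BMI, relationship, seniority, work type, shift work, study
site), a 57-column design. Zero-crossings count sign changes of the
mean-centered observed series in temporal order, with exact zeros inheriting
the previous sign; mean-centering makes the statistic scale-free since no
reference level is otherwise canonical. Skewness/kurtosis of constant or
too-short series are null. Sequence samples are within-window
median-imputed (fallback: participant median, then cohort median),
tail-padded to 30 days with an explicit validity length that models must
consume; padded rows are inert by masking, verified bit-exactly.

ICC is the one-way random-effects ICC(1) from ANOVA mean squares with the
unbalanced-group correction `n0 = (N − Σn_i²/N)/(k − 1)`, clipped at 0.

Recursive feature elimination reduces the aggregate design to exactly 15
columns per training fold. The base estimator is ridge regression
(continuous targets) or L2 logistic regression (binary), step size 1; the
choice is configurable because no canonical estimator exists for this step,
and selections are moderately sensitive to it (linear bases favour the
mean/percentile aggregates; tree bases favour dispersion statistics).

## Models

The sequential scorer is a GRU (default one layer, hidden size 16) over the
first `valid_length` daily observations; the final hidden state is
concatenated with the time-invariant covariates and passed through a
single-hidden-layer feed-forward head with dropout (training mode only) to
one scalar. The pairwise ranker is siamese: the *same* parameter set scores
both windows of a pair, and the score difference enters either the margin
ranking loss `max(0, −y·(ŷ_i − ŷ_j) + ε)` with ε = 0.5, or the
RankNet-style binary cross-entropy of `sigmoid(ŷ_i − ŷ_j)` (computed in
softplus form, stable to |Δ| ≈ 700). Training pairs require a target gap of
at least 0.5 on the 1–7 scale, because smaller self-report differences are
not considered meaningful; pairs may link two windows of one participant
(subject-wise fold splits keep this leak-free across folds; a toggle
disables it). Hard pair labels are used throughout — soft RankNet targets
for near-ties are moot once sub-gap pairs are excluded.

All gradients come from a small reverse-mode autodiff engine written over
numpy and verified against central finite differences (max observed error
~1e-10). Optimization is Adam; weights use uniform fan-in initialization,
seed-controlled. Early stopping holds out 20% of training participants
(subject-wise), rebuilds pairs within each side, and stops after 10 epochs
without validation improvement, restoring the best-epoch weights. The
reference training configuration is `learning_rate = 1e-5` for up to 100
epochs; the reduced-scale protocol configurations pair a shorter schedule
(≤ 30 epochs, pair count capped per epoch) with Adam's canonical 1e-3 step
so the optimizer travels a commensurate distance in far less wall time.

Classification dichotomizes scores at the published cut-offs (PF 3.5,
CW 2.83, EE 2.75); the boundary counts as high risk (the choice only
affects measure-zero events on continuous scores). Tabular baselines are
scikit-learn estimators (LR/LDA/QDA/RF; lasso/ridge/elastic net/RF) behind a
uniform fit/predict surface with small hyperparameter grids searched on
3 subject-wise inner folds (the inner fold count is a default, not a claim).

## Evaluation

Folds are subject-wise and stratified: each participant's mean window target
is binned into quartiles and bins are dealt round-robin after a seeded
shuffle. Metrics: Spearman ρ (midrank ties; undefined on zero-variance
inputs and reported missing), NDCG with exponential gains
`(2^rel − 1)/log2(rank + 1)` where relevance is the raw 1–7 score (a
binned-gain variant can be obtained by pre-transforming the relevance
vector), ROC-AUC, and F1 of the high-risk class at probability 0.5. NDCG
ties are broken stably by window id; an all-zero relevance list is defined
as NDCG 1. Reference baselines: a biased random guesser sampling the
training label mix, a constant mean predictor, the mean NDCG of 1,000
random orderings per fold, and a pairwise-trained feed-forward ranker on
time-invariant covariates only. Fold × seed values are summarized as
median (p25–p75); comparisons use one-sided Wilcoxon signed-rank tests at
α = 0.05, paired over fold(/seed) values, with all-zero difference vectors
reported as non-significant.

## Reference protocols and problem sizes

`burnrank.protocols` pre-registers two desk-scale experiments (150
participants × 270 days, 10 outer folds): *signal recovery* at coupling 0.6,
where the siamese margin ranker is compared against the invariant and
random rankers, and *null calibration* at coupling 0, replicated over ten
seeds with a further-shortened schedule (10 epochs — under the null there is
nothing to learn; the quantity of interest is the spread of test
correlations). `scripts/acceptance.py` runs both plus ICC recovery and
writes the computed quantities as JSON.

## Known limitations

Single-CPU numpy training limits practical cohort sizes to a few hundred
participants. The simulator's independence of demographics and severity
makes the invariant baseline uninformative by design; planted covariate
effects must be added explicitly to study it. NDCG with exponential gains on
a 1–7 scale is dominated by the top-scoring windows, so small test folds
give noisy NDCG values. The λ-gradient/listwise extensions of the pairwise
ranker and joint multi-subscale modeling are out of scope.
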