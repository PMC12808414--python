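"""Configuration objects shared across the pipeline.

All stochastic stages are driven by a single integer seed carried in the
relevant config; identical configs therefore yield identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented domain."""


#: The seven daily wearable-derived features, in canonical column order.
TIME_VARYING_FEATURES: Tuple[str, ...] = (
    "total_sleep_time",
    "waso",
    "restorative_sleep_pct",
    "median_waking_hr",
    "rest_hr",
    "overnight_stress",
    "sedentary_pct",
)

#: The eight time-invariant covariates, in canonical column order.
#: `site` encodes the study site (two recruitment countries).
TIME_INVARIANT_COVARIATES: Tuple[str, ...] = (
    "gender",
    "age",
    "bmi",
    "relationship",
    "seniority",
    "work_type",
    "shift_work",
    "site",
)

#: SMBM-14 item partition: indices (0-based) of the items feeding each subscale.
#: Default is the standard 6 physical-fatigue / 5 cognitive-weariness /
#: 3 emotional-exhaustion split.
DEFAULT_SMBM_MAP: Dict[str, Tuple[int, ...]] = {
    "pf": (0, 1, 2, 3, 4, 5),
    "cw": (6, 7, 8, 9, 10),
    "ee": (11, 12, 13),
}

#: High-risk cut-offs on the 1-7 subscale scores.
SMBM_CUTOFFS: Dict[str, float] = {"pf": 3.5, "cw": 2.83, "ee": 2.75}


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


def _default_icc_targets() -> Dict[str, float]:
    # Cardiac features show higher between-person variance than sleep,
    # stress and activity summaries.
    return {
        "total_sleep_time": 0.35,
        "waso": 0.35,
        "restorative_sleep_pct": 0.30,
        "median_waking_hr": 0.60,
        "rest_hr": 0.65,
        "overnight_stress": 0.40,
        "sedentary_pct": 0.45,
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic longitudinal cohort generator.

    Defaults emulate the monitored-worker study conditions: ~9 months of
    daily wear data, monthly 14-item surveys with 28% completion of the
    expected entries, daily wearing adherence ~66% and night adherence ~83%.
    """

    n_participants: int = 200
    study_days: int = 270
    survey_interval_days: int = 30
    survey_response_prob: float = 0.28
    latent_coupling: float = 0.5
    icc_targets: Dict[str, float] = field(default_factory=_default_icc_targets)
    wear_adherence_rate: float = 0.664
    night_adherence_rate: float = 0.827
    manual_sleep_prob: float = 0.05
    severity_linked_missingness: float = 0.0
    smbm_map: Dict[str, Tuple[int, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SMBM_MAP.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if self.study_days < 2 * self.survey_interval_days:
            raise ConfigError("study_days must be >= 2 * survey_interval_days")
        if self.survey_interval_days < 1:
            raise ConfigError("survey_interval_days must be positive")
        for name in (
            "survey_response_prob",
            "wear_adherence_rate",
            "night_adherence_rate",
            "manual_sleep_prob",
        ):
            _check_prob(name, getattr(self, name))
        if not (0.0 <= self.latent_coupling <= 1.0):
            raise ConfigError("latent_coupling must lie in [0, 1]")
        for feat, icc in self.icc_targets.items():
            if feat not in TIME_VARYING_FEATURES:
                raise ConfigError(f"icc_targets names unknown feature {feat!r}")
            if not (0.0 <= icc <= 1.0):
                raise ConfigError(f"icc_targets[{feat!r}] must lie in [0, 1]")
        items = sorted(i for idx in self.smbm_map.values() for i in idx)
        if items != list(range(14)):
            raise ConfigError("smbm_map must partition items 0..13")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["smbm_map"] = {k: list(v) for k, v in self.smbm_map.items()}
        return d


@dataclass
class WindowConfig:
    """Window-extraction thresholds (see the windowing module)."""

    min_length: int = 20
    max_length: int = 30
    min_adherent_days: int = 10
    min_adherent_nights: int = 10
    min_cumulative_days: int = 14
    wear_threshold: float = 0.70
    min_sleep_minutes: float = 120.0
    #: If True, only assessments that produced a valid window reset the
    #: "previous submission" anchor; default anchors on every retained
    #: submission regardless of window validity.
    anchor_on_valid_windows_only: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.min_length <= self.max_length):
            raise ConfigError("need 1 <= min_length <= max_length")
        _check_prob("wear_threshold", self.wear_threshold)


@dataclass
class EncoderConfig:
    """Recurrent encoder + feed-forward head architecture."""

    hidden_size: int = 16
    n_layers: int = 1
    dropout: float = 0.2
    head_hidden_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ConfigError("hidden_size must be >= 1")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must lie in [0, 1)")


VALID_LOSSES = ("bce_class", "mse_reg", "rank_bce", "rank_margin")


@dataclass
class TrainConfig:
    """Optimization settings for the recurrent models."""

    learning_rate: float = 1e-5
    max_epochs: int = 100
    patience: int = 10
    loss: str = "rank_margin"
    margin_eps: float = 0.5
    pair_gap: float = 0.5
    batch_size: int = 128
    max_pairs_per_epoch: int = 0  # 0 = uncapped
    val_fraction: float = 0.2
    allow_within_subject_pairs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.margin_eps <= 0:
            raise ConfigError("margin_eps must be > 0")
        if self.pair_gap < 0:
            raise ConfigError("pair_gap must be >= 0")
        if self.loss not in VALID_LOSSES:
            raise ConfigError(f"loss must be one of {VALID_LOSSES}")
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigError("val_fraction must lie in (0, 1)")
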