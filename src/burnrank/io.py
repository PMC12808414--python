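"""Table schemas, readers/writers and experiment configuration files.

Cohort tables round-trip through CSV or Parquet (chosen by extension).
Every artifact written by the pipeline gets a JSON metadata sidecar with
the package version, a hash of the generating config and the seed, enough
to regenerate it exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .config import (
    CohortConfig,
    ConfigError,
    EncoderConfig,
    TIME_VARYING_FEATURES,
    TrainConfig,
    WindowConfig,
)


class SchemaError(ValueError):
    """A table violates its documented schema."""


PROFILE_COLUMNS = [
    "participant_id", "gender", "age", "bmi", "relationship", "seniority",
    "work_type", "shift_work", "site",
    "latent_severity_baseline", "latent_severity_walk_sd",
]
DAILY_COLUMNS = [
    "participant_id", "day_index", "wear_fraction",
    *TIME_VARYING_FEATURES,
    "sleep_manual_flag", "main_sleep_duration",
]
ASSESSMENT_COLUMNS = [
    "participant_id", "day_index",
    *[f"item_{k:02d}" for k in range(1, 15)],
    "pf_score", "cw_score", "ee_score", "overall_score", "is_baseline",
]


def _check_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing column(s): {', '.join(missing)}")


def _check_unique_days(df: pd.DataFrame, table: str) -> None:
    dup = df.duplicated(subset=["participant_id", "day_index"], keep=False)
    if dup.any():
        idx = list(df.index[dup])
        raise SchemaError(
            f"{table} table has duplicate (participant_id, day_index) rows at indices {idx}"
        )


def _write_table(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def config_hash(config) -> str:
    if hasattr(config, "to_dict"):
        d = config.to_dict()
    else:
        d = asdict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def write_metadata(path: Path, config, seed: Optional[int]) -> None:
    meta = {
        "package_version": __version__,
        "config_hash": config_hash(config) if config is not None else None,
        "config": config.to_dict() if hasattr(config, "to_dict") else (
            asdict(config) if config is not None else None
        ),
        "seed": seed,
    }
    path.write_text(json.dumps(meta, indent=2))


def write_cohort(
    tables: Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    directory: str | Path,
    fmt: str = "csv",
    config: Optional[CohortConfig] = None,
) -> Dict[str, Path]:
    """Write (profiles, daily, assessments) plus a metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    profiles, daily, assessments = tables
    paths = {}
    for name, df in (("profiles", profiles), ("daily", daily), ("assessments", assessments)):
        p = directory / f"{name}.{fmt}"
        _write_table(df, p)
        paths[name] = p
    write_metadata(
        directory / "metadata.json", config, config.seed if config else None
    )
    return paths


def read_cohort(directory: str | Path, fmt: str = "csv"):
    """Read and validate the three cohort tables."""
    directory = Path(directory)
    profiles = _read_table(directory / f"profiles.{fmt}")
    daily = _read_table(directory / f"daily.{fmt}")
    assessments = _read_table(directory / f"assessments.{fmt}")
    _check_columns(profiles, PROFILE_COLUMNS, "profiles")
    _check_columns(daily, DAILY_COLUMNS, "daily")
    _check_columns(assessments, ASSESSMENT_COLUMNS, "assessments")
    if profiles["participant_id"].duplicated().any():
        raise SchemaError("profiles table has duplicate participant_id values")
    _check_unique_days(daily, "daily")
    _check_unique_days(assessments, "assessments")
    daily["sleep_manual_flag"] = daily["sleep_manual_flag"].astype(bool)
    assessments["is_baseline"] = assessments["is_baseline"].astype(bool)
    return profiles, daily, assessments


def write_windows(windows: pd.DataFrame, path: str | Path) -> None:
    _write_table(windows, Path(path))


def read_windows(path: str | Path) -> pd.DataFrame:
    df = _read_table(Path(path))
    _check_columns(
        df,
        ["window_id", "participant_id", "start_day", "end_day", "length_days"],
        "windows",
    )
    return df


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

KNOWN_SECTIONS = {"cohort", "windowing", "encoder", "training", "evaluation"}


def load_pipeline_config(path: str | Path) -> Dict[str, object]:
    """Parse a YAML pipeline config into validated config objects.

    Unknown top-level keys are rejected; each section maps onto its
    dataclass so invalid values fail on load, not mid-run.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    unknown = set(raw) - KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    out: Dict[str, object] = {}
    if "cohort" in raw:
        c = dict(raw["cohort"])
        if "smbm_map" in c:
            c["smbm_map"] = {k: tuple(v) for k, v in c["smbm_map"].items()}
        out["cohort"] = CohortConfig(**c)
    if "windowing" in raw:
        out["windowing"] = WindowConfig(**raw["windowing"])
    if "encoder" in raw:
        out["encoder"] = EncoderConfig(**raw["encoder"])
    if "training" in raw:
        out["training"] = TrainConfig(**raw["training"])
    out["evaluation"] = dict(raw.get("evaluation", {}))
    return out


def save_pipeline_config(config: Dict[str, object], path: str | Path) -> None:
    serial = {}
    for key, value in config.items():
        if hasattr(value, "to_dict"):
            serial[key] = value.to_dict()
        elif hasattr(value, "__dataclass_fields__"):
            serial[key] = asdict(value)
        else:
            serial[key] = value
    Path(path).write_text(yaml.safe_dump(serial, sort_keys=False))
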