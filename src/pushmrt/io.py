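"""File formats, configuration and run manifests.

The interchange format is a single long-format CSV (comma-separated,
UTF-8, "." decimal, header required) with one row per user x decision
point.  ``prob`` is empty on non-considered rows; all indicator columns
are 0/1.  Configuration is a YAML file with ``trial`` / ``cohort`` /
``outcome_model`` / ``model_spec`` sections; every design default (89
days, 6 slots, 50% randomization, the inactivity wait buckets) can be
overridden, and unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, OutcomeModelParams
from .design import RECORD_COLUMNS, AvailabilityRuleTable, TrialConfig
from .emee import ModelMatrixSpec

__all__ = [
    "SchemaError",
    "ConfigError",
    "read_records",
    "write_records",
    "validate_records",
    "RunConfig",
    "load_config",
    "RunManifest",
    "file_digest",
]

COVARIATE_COLUMNS = [
    "week_in_study",
    "which_day",
    "days_since_chart",
    "pushed_indicator",
    "push_success_ratio",
    "has_charted_10",
]

_KNOWN_COLUMNS = set(RECORD_COLUMNS) | set(COVARIATE_COLUMNS)
_BINARY_COLUMNS = ["available", "considered", "push", "outcome_24h"]


class SchemaError(ValueError):
    """A decision-record table violates the declared schema."""


class ConfigError(ValueError):
    """A configuration file is invalid; the message lists all violations."""


def write_records(table: pd.DataFrame, path) -> None:
    """Write a decision-record table as CSV (NaN prob written empty)."""
    table.to_csv(path, index=False)


def read_records(path, *, validate: bool = True) -> pd.DataFrame:
    """Read and (by default) validate a decision-record CSV.

    Round-trips exactly with :func:`write_records`: values and row order
    are preserved.  Validation checks column membership, binary flags,
    the considered/available/push implications, and that ``prob`` lies in
    (0, 1) exactly on considered rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    extra = sorted(set(df.columns) - _KNOWN_COLUMNS)
    problems = []
    if missing:
        problems.append(f"missing columns: {missing}")
    if extra:
        problems.append(f"unknown columns: {extra}")
    if problems:
        raise SchemaError("; ".join(problems))
    if validate:
        validate_records(df)
    for col in ["user_id", "day", "slot"] + _BINARY_COLUMNS:
        df[col] = df[col].astype(np.int64)
    return df


def validate_records(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming the first bad row of each kind."""
    problems = []

    def first_bad(mask, message):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            problems.append(f"{message} (first at row {row})")

    for col in _BINARY_COLUMNS:
        first_bad(~df[col].isin([0, 1]), f"column {col!r} not binary")
    if problems:  # implications below assume binary flags
        raise SchemaError("; ".join(problems))
    first_bad(
        (df["considered"] == 1) & (df["available"] != 1),
        "considered=1 requires available=1",
    )
    first_bad(
        (df["push"] == 1) & (df["considered"] != 1),
        "push=1 requires considered=1",
    )
    cons = df["considered"] == 1
    first_bad(
        cons & ~((df["prob"] > 0) & (df["prob"] < 1)),
        "prob must lie in (0,1) on considered rows",
    )
    first_bad(cons.groupby([df["user_id"], df["day"]]).transform("sum") > 1,
              "more than one considered slot in a user-day")
    if problems:
        raise SchemaError("; ".join(problems))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of all configurable pieces of a run."""

    trial: TrialConfig
    cohort: CohortConfig
    outcome_model: OutcomeModelParams
    model_spec: ModelMatrixSpec


_SECTION_FIELDS = {
    "trial": {
        "n_days", "slot_times", "randomization_prob", "rule_table",
        "weekend_morning_blocked", "start_weekday",
    },
    "cohort": {"n_users", "share_female", "age_shares", "share_bmi25"},
    "outcome_model": {
        "alpha_star", "beta_star", "moderator_terms", "user_sd", "prob_cap",
        "hidden_weekend_uplift",
    },
    "model_spec": {"moderator_terms", "control_terms", "p_tilde"},
}


def load_config(path) -> RunConfig:
    """Load a YAML configuration, applying defaults for anything omitted.

    An empty file yields the full default configuration.  All violations
    (unknown sections/keys, invalid values) are collected and reported in
    one :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("top level of the config file must be a mapping")
    errors: list[str] = []
    for section in sorted(set(raw) - set(_SECTION_FIELDS)):
        errors.append(f"unknown section {section!r}")
    clean: dict[str, dict] = {}
    for section, allowed in _SECTION_FIELDS.items():
        body = raw.get(section) or {}
        if not isinstance(body, Mapping):
            errors.append(f"section {section!r} must be a mapping")
            body = {}
        for key in sorted(set(body) - allowed):
            errors.append(f"unknown key {section}.{key}")
        clean[section] = {k: v for k, v in body.items() if k in allowed}

    trial = cohort = outcome = spec = None

    tr = dict(clean["trial"])
    if "slot_times" in tr:
        tr["slot_times"] = tuple(float(t) for t in tr["slot_times"])
    if "rule_table" in tr:
        try:
            buckets = tuple(
                (float(lo), math.inf if hi in ("inf", ".inf", None) else float(hi), int(w))
                for lo, hi, w in tr["rule_table"]
            )
            tr["rule_table"] = AvailabilityRuleTable(buckets=buckets)
        except (TypeError, ValueError) as exc:
            errors.append(f"trial.rule_table: {exc}")
            del tr["rule_table"]
    try:
        trial = TrialConfig(**tr)
    except (TypeError, ValueError) as exc:
        errors.append(f"trial: {exc}")

    co = dict(clean["cohort"])
    if "age_shares" in co:
        co["age_shares"] = tuple(float(s) for s in co["age_shares"])
    try:
        cohort = CohortConfig(**co)
    except (TypeError, ValueError) as exc:
        errors.append(f"cohort: {exc}")

    om = dict(clean["outcome_model"])
    moderator_terms = tuple(om.pop("moderator_terms", ()))
    if "beta_star" in om:
        om["beta_star"] = tuple(float(b) for b in om["beta_star"])
    try:
        outcome = OutcomeModelParams(
            moderator_spec=ModelMatrixSpec(moderator_terms=moderator_terms), **om
        )
    except (TypeError, ValueError) as exc:
        errors.append(f"outcome_model: {exc}")

    ms = dict(clean["model_spec"])
    for key in ("moderator_terms", "control_terms"):
        if key in ms:
            ms[key] = tuple(ms[key])
    try:
        spec = ModelMatrixSpec(**ms)
    except (TypeError, ValueError) as exc:
        errors.append(f"model_spec: {exc}")

    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(trial=trial, cohort=cohort, outcome_model=outcome, model_spec=spec)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def file_digest(path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output.

    For deterministic stages, a manifest plus the recorded inputs and
    seeds reproduces the outputs bit for bit.
    """

    command: str
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    version: str = "pushmrt 0.1.0"

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable) + "\n",
            encoding="utf-8",
        )


def _jsonable(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, Path):
        return str(obj)
    if obj is math.inf:
        return "inf"
    return str(obj)
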