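"""Delimited-text formats, configuration files, and dataset validation.

Everything on disk is header-carrying delimited text: missing heart rates
are empty fields, temperatures are degC, and every file written by the
pipeline starts with ``#`` comment lines recording the package version,
seed and a hash of the generating configuration, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import DATASET_COLUMNS, PopulationConfig, TraitModel

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "config_hash",
    "write_table",
    "read_table",
    "read_dataset",
    "ValidationReport",
    "validate_dataset",
]

_TRAIT_FIELDS = ("f_h0", "t_ab", "t_peak", "t_arr")


def config_to_dict(config: PopulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["n_per_group"] = {float(k): int(v) for k, v in config.n_per_group.items()}
    return d


def config_from_dict(d: dict) -> PopulationConfig:
    d = dict(d)
    if "seed" not in d:
        raise ValueError("config must specify a seed")
    for name in _TRAIT_FIELDS:
        if name in d and isinstance(d[name], dict):
            d[name] = TraitModel(**d[name])
    if "n_per_group" in d:
        d["n_per_group"] = {float(k): int(v) for k, v in d["n_per_group"].items()}
    return PopulationConfig(**d)


def load_config(path) -> PopulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: PopulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: PopulationConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a table as comma-delimited text with ``#`` metadata lines.

    Floats use a canonical shortest-round-trip representation so identical
    inputs produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False, na_rep="")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format heart-rate dataset written by the pipeline."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset at {path} lacks required columns {missing}")
    df["arrhythmic"] = df["arrhythmic"].astype(bool)
    return df[DATASET_COLUMNS]


@dataclass
class ValidationReport:
    """Outcome of structural checks on a dataset file."""

    n_rows: int
    n_individuals: int
    counts_per_group: dict[float, int]
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        lines = [
            f"rows: {self.n_rows}",
            f"individuals: {self.n_individuals}",
            "individuals per incubation group: "
            + ", ".join(f"{g}C: {n}" for g, n in sorted(self.counts_per_group.items())),
        ]
        if self.violations:
            lines.append(f"violations ({len(self.violations)}):")
            lines.extend(f"  - {v}" for v in self.violations)
        else:
            lines.append("all invariants satisfied")
        return "\n".join(lines)


def validate_dataset(data) -> ValidationReport:
    """Check dataset invariants and count individuals per incubation group.

    Checks: every individual covers the same step set; heart rate missing
    exactly on arrhythmic rows; arrhythmia flags upward-closed in
    temperature within each individual. Violations name the offending
    individual and row.
    """
    df = read_dataset(data) if not isinstance(data, pd.DataFrame) else data
    if len(df) == 0:
        raise ValueError("empty dataset")
    violations: list[str] = []

    bad_missing = df["f_H_bpm"].isna() != df["arrhythmic"]
    for i in df.index[bad_missing]:
        row = df.loc[i]
        kind = "f_H present on arrhythmic row" if row["arrhythmic"] else "f_H missing on non-arrhythmic row"
        violations.append(f"row {i} (individual {row['individual_id']}): {kind}")

    step_sets = df.groupby("individual_id")["step_temp_C"].apply(
        lambda s: tuple(sorted(s))
    )
    reference = step_sets.mode().iloc[0]
    for ind, steps in step_sets.items():
        if steps != reference:
            violations.append(
                f"individual {ind}: step set {steps} differs from protocol {reference}"
            )

    for ind, grp in df.sort_values("step_temp_C").groupby("individual_id"):
        flags = grp["arrhythmic"].to_numpy().astype(int)
        if np.any(np.diff(flags) < 0):
            violations.append(
                f"individual {ind}: arrhythmia flags not upward-closed in temperature"
            )

    counts = (
        df.drop_duplicates("individual_id").groupby("incubation_C").size().to_dict()
    )
    return ValidationReport(
        n_rows=len(df),
        n_individuals=df["individual_id"].nunique(),
        counts_per_group={float(k): int(v) for k, v in counts.items()},
        violations=violations,
    )
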