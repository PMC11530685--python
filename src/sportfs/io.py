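"""CSV and configuration readers/writers.

The on-disk table format is deliberately plain: comma-separated, UTF-8,
header row, empty field = missing value.  Run configuration round-trips
through YAML with strict schema validation (unknown keys are rejected with
a nearest-key suggestion), and every saved config records the resolved seed
so a run can be reproduced exactly.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datagen import GeneratorSpec, LabeledDataset
from .forest import ForestConfig
from .optim import OptimizerConfig

__all__ = [
    "ConfigError",
    "RunConfig",
    "read_feature_csv",
    "write_feature_csv",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised for malformed configuration files."""


def read_feature_csv(path, label_column: str = "label") -> LabeledDataset:
    """Read a feature table with a label column from CSV.

    Empty fields become NaN (missing).  Non-numeric feature cells and
    duplicate header names are reported with their location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header:
        raise ValueError(f"{path}: empty file or missing header row")
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate header names {sorted(dupes)}")
    if label_column not in header:
        raise ValueError(f"{path}: label column {label_column!r} not in header")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] != len(header):
        raise ValueError(f"{path}: ragged rows")
    labels = raw[label_column].astype(str)
    features = raw.drop(columns=[label_column])
    numeric = {}
    for col in features.columns:
        series = features[col].replace("", np.nan)
        converted = pd.to_numeric(series, errors="coerce")
        bad = converted.isna() & series.notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {series.iloc[row]!r} in column "
                f"{col!r}, line {row + 2}"  # +1 header, +1 one-based
            )
        numeric[col] = converted
    frame = pd.DataFrame(numeric, columns=features.columns)
    manifest = path.with_suffix(".manifest.json")
    truth: frozenset[str] = frozenset()
    if manifest.exists():
        import json

        truth = frozenset(json.loads(manifest.read_text()).get("truth", []))
        truth = truth & set(frame.columns)
    return LabeledDataset(frame, labels.rename("label"), truth)


def write_feature_csv(dataset: LabeledDataset, path,
                      label_column: str = "label") -> None:
    dataset.to_csv(path, label_column=label_column)


# -- run configuration -----------------------------------------------------


@dataclass
class PipelineOptions:
    train_ratio: float = 0.7
    k_folds: int = 5
    tree_grid: tuple[int, ...] = (50, 100, 150, 200)
    depth_grid: tuple[int, ...] = (10, 20, 30, 40)


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    forest: ForestConfig = field(default_factory=ForestConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    pipeline: PipelineOptions = field(default_factory=PipelineOptions)
    output_dir: str = "sportfs_out"
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        eff = self.generator.effect_sizes
        d["generator"]["effect_sizes"] = (
            float(eff) if np.isscalar(eff) else [float(e) for e in eff]
        )
        d["pipeline"]["tree_grid"] = list(self.pipeline.tree_grid)
        d["pipeline"]["depth_grid"] = list(self.pipeline.depth_grid)
        return d


_SECTIONS = {
    "generator": GeneratorSpec,
    "forest": ForestConfig,
    "optimizer": OptimizerConfig,
    "pipeline": PipelineOptions,
}
_TOP_KEYS = set(_SECTIONS) | {"output_dir", "seed"}


def _reject_unknown(given, allowed, context):
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, list(allowed), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {context}{suffix}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill omissions."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "top level")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        payload = data.get(section, {}) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: section {section!r} must be a mapping")
        fields = set(cls.__dataclass_fields__)
        _reject_unknown(payload, fields, f"section {section!r}")
        if section == "generator" and "effect_sizes" in payload:
            e = payload["effect_sizes"]
            payload["effect_sizes"] = tuple(e) if isinstance(e, list) else e
        if section == "pipeline":
            for g in ("tree_grid", "depth_grid"):
                if g in payload:
                    payload[g] = tuple(payload[g])
        try:
            kwargs[section] = cls(**payload)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid section {section!r}: {exc}") from exc
    cfg = RunConfig(
        output_dir=str(data.get("output_dir", "sportfs_out")),
        seed=int(data.get("seed", 0)),
        **kwargs,
    )
    cfg.generator.validate()
    cfg.forest.validate()
    cfg.optimizer.validate()
    return cfg


def save_config(config: RunConfig, path) -> None:
    """Write the fully-resolved configuration (defaults made explicit)."""
    Path(path).write_text(
        yaml.safe_dump(config.as_dict(), sort_keys=True, default_flow_style=False)
    )
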