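"""Tabular I/O, run configuration and the scaling workflow.

Feature tables travel as delimited text in wide format: first column the
feature identifier, remaining columns one per sample.  Group labels
(control/case) come from a two-column sidecar file or an in-memory
mapping.  A RunConfig collects every knob of the scaling workflow and is
round-trippable through a plain YAML file, so each CLI flag has a config
twin.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import cohort, core

__all__ = [
    "RunConfig",
    "read_feature_table",
    "write_feature_table",
    "read_group_map",
    "run_scale_workflow",
]

log = logging.getLogger("percept")


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_group_map(path: str | Path, sep: str | None = None) -> pd.Series:
    """Two-column sample -> group file (header optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"group map {path} needs two columns (sample, group)")
    first = df.iloc[0, 1].strip().lower()
    if first not in (cohort.CONTROL, cohort.CASE):  # header row present
        df = df.iloc[1:]
    groups = pd.Series(
        df.iloc[:, 1].str.strip().str.lower().to_numpy(),
        index=df.iloc[:, 0].str.strip().to_numpy(),
    )
    return groups


def read_feature_table(
    path: str | Path,
    groups: Mapping[str, str] | pd.Series | str | Path | None = None,
    value_space: str = "intensity",
    sep: str | None = None,
) -> cohort.FeatureTable:
    """Parse a wide delimited table into a validated FeatureTable.

    Dialect is inferred from the extension (.tsv/.tab/.txt tab, else
    comma) unless ``sep`` is given.  Non-numeric cells become nulls and
    their count is logged; duplicate feature ids raise.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, dtype=str)
    if raw.empty:
        raise ValueError(f"{path} contains no data rows")
    raw.index = raw.index.astype(str)
    raw.index.name = "feature_id"
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = int(numeric.isna().sum().sum() - raw.isna().sum().sum())
    if bad:
        log.warning("%s: %d non-numeric cell(s) treated as missing", path.name, bad)
    if isinstance(groups, (str, Path)):
        groups = read_group_map(groups)
    elif isinstance(groups, Mapping):
        groups = pd.Series(groups)
    if groups is not None:
        groups = groups.reindex(numeric.columns)
        if groups.isna().any():
            missing = list(numeric.columns[groups.isna()])
            raise ValueError(f"samples missing a group label: {missing[:5]}")
    return cohort.FeatureTable(data=numeric, groups=groups, value_space=value_space)


def write_feature_table(table: cohort.FeatureTable, path: str | Path,
                        sep: str | None = None) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path, sep))


@dataclass
class RunConfig:
    """Everything the scaling workflow needs, serializable to YAML.

    ``penalty`` is a number or "auto" (resolve F = 10 * n per feature).
    ``thresholds`` may pre-specify (lower, upper); otherwise they are
    derived from the control cohort's pseudo-control distribution.
    """

    table: str = ""
    groups: str | None = None
    value_space: str = "intensity"
    m0: float = 0.0
    penalty: float | str = "auto"
    alpha: float = 0.05
    coverage: float = 0.90
    seed: int = 0
    thresholds: tuple[float, float] | None = None
    out_dir: str = "percept_out"
    full_precision: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.penalty, str):
            if self.penalty != "auto":
                self.penalty = float(self.penalty)
        if self.thresholds is not None:
            self.thresholds = (float(self.thresholds[0]), float(self.thresholds[1]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        if payload["thresholds"] is not None:
            payload["thresholds"] = list(payload["thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _resolve_seed(seed: int, stage: str) -> int:
    """Per-stage substream of the single run seed, stable across stages
    and processes (CRC32 of the stage name as the spawn key)."""
    key = zlib.crc32(stage.encode()) % (2**31)
    child = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)


STAGE_THRESHOLDS = "thresholds"


def run_scale_workflow(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Ratio computation, thresholds, PERCEPT scaling and categorization.

    Reads the configured table; intensity tables are converted to per-donor
    log2 ratios against the control mean and thresholds are derived from
    the control cohort unless given explicitly.  Writes
    ``scaled_features.csv`` and ``summary.json`` under ``out_dir`` and
    returns them.  Outputs are deterministic under a fixed config.
    """
    table = read_feature_table(config.table, groups=config.groups,
                               value_space=config.value_space)
    thresholds = None
    if config.thresholds is not None:
        thresholds = cohort.EffectThresholds(*config.thresholds, alpha=config.alpha)

    if config.value_space == "intensity":
        if thresholds is None:
            thresholds = cohort.pseudo_control_thresholds(
                table,
                coverage=config.coverage,
                seed=_resolve_seed(config.seed, STAGE_THRESHOLDS),
                alpha=config.alpha,
            )
        ratios = cohort.abundance_ratios(table)
    elif config.value_space == "log2_ratio":
        ratios = table
        if thresholds is None:
            raise ValueError(
                "log2_ratio input needs explicit thresholds (no control "
                "intensities to derive them from)"
            )
    else:
        raise ValueError("value_space must be 'intensity' or 'log2_ratio'")

    F = None if config.penalty == "auto" else float(config.penalty)
    result = cohort.scale_table(ratios, m0=config.m0, F=F, thresholds=thresholds)

    counts = result["category"].value_counts().to_dict()
    total = int(result["category"].notna().sum())
    resolved_F = (
        "10*n (per feature)" if F is None else F
    )
    if F is None:
        unique_n = sorted(set(result["n"]))
        if len(unique_n) == 1:
            resolved_F = 10.0 * unique_n[0]
    summary = {
        "n_features": int(len(result)),
        "m0": config.m0,
        "penalty": resolved_F,
        "alpha": config.alpha,
        "thresholds": {"lower": thresholds.lower, "upper": thresholds.upper},
        "seed": config.seed,
        "category_counts": {k: int(v) for k, v in counts.items()},
        "category_percent": {
            k: round(100.0 * v / total, 4) for k, v in counts.items() if total
        },
    }
    log.info(
        "scale workflow: F=%s m0=%s alpha=%s thresholds=(%.6g, %.6g) seed=%d",
        resolved_F, config.m0, config.alpha,
        thresholds.lower, thresholds.upper, config.seed,
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = result if config.full_precision else result.round(6)
    out.to_csv(out_dir / "scaled_features.csv")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return result, summary
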