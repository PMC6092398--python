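"""Run configuration, table I/O and provenance records.

A run configuration is a YAML file with one block per module; unknown keys
are rejected by name so typos cannot silently fall back to defaults.  Tables
are written as TSV with 6-significant-digit floats and a deterministic column
order, and every CLI run emits a JSON provenance record (seed, config hash,
package version) sufficient to reproduce deterministic outputs bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .population import ModelParams
from .tracegen import TelegraphParams
from .vanzon import VanZonParams

__all__ = ["RunConfig", "load_config", "write_table", "write_provenance"]


@dataclass(frozen=True)
class MetricsConfig:
    burn_in_h: float = 30.0
    smooth_window_h: float = 2.0
    amplitude_threshold: float = 10.0
    min_peaks: int = 3
    duration_h: float = 200.0
    n_seeds: int = 5


@dataclass(frozen=True)
class AfmConfig:
    pixel_nm: float = 0.1
    tip_radius_nm: float = 0.5
    half_angle_deg: float = 10.0
    angle_is_full: bool = False
    per_residue: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration: per-module blocks plus global settings."""

    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"
    population: ModelParams = field(default_factory=ModelParams)
    telegraph: TelegraphParams = field(
        default_factory=lambda: TelegraphParams(tau_bound=1.12, tau_unbound=5.47)
    )
    vanzon: VanZonParams = field(default_factory=VanZonParams)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    afm: AfmConfig = field(default_factory=AfmConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_BLOCKS = {
    "population": ModelParams,
    "telegraph": TelegraphParams,
    "vanzon": VanZonParams,
    "metrics": MetricsConfig,
    "afm": AfmConfig,
}
_GLOBALS = {"seed": int, "outdir": str, "log_level": str}


def _build_block(cls, data: Mapping[str, Any], block: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block '{block}'"
        )
    return cls(**data)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing blocks and keys take their defaults; an empty (or absent) file
    yields the all-defaults configuration; unknown keys raise a ValueError
    naming the offending key and block.
    """
    data: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded)}")
        data = loaded
    unknown = set(data) - set(_BLOCKS) - set(_GLOBALS)
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, caster in _GLOBALS.items():
        if key in data:
            kwargs[key] = caster(data[key])
    for block, cls in _BLOCKS.items():
        if block in data:
            blockdata = data[block] or {}
            if not isinstance(blockdata, dict):
                raise ValueError(f"config block '{block}' must be a mapping")
            kwargs[block] = _build_block(cls, blockdata, block)
    return RunConfig(**kwargs)


def write_table(rows, path: str | Path, dialect: str = "tsv") -> None:
    """Write rows (DataFrame or list of dicts) as TSV/CSV.

    Floats are rendered at 6 significant digits; the column order of the
    input is preserved (deterministic for dict rows in insertion order).
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown table dialect {dialect!r}")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def write_provenance(path: str | Path, config: RunConfig, **extra) -> None:
    """Emit a JSON provenance record for a run."""
    from . import __version__

    record = dict(
        version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        **extra,
    )
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
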