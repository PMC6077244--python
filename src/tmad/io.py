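"""Reading/writing expirograms and run configurations.

All tabular I/O is comma-separated text with a documented header; an
expirogram file carries the columns ``time_s``, ``volume_ml``, ``co_ppb``
and optionally ``flow_ml_s`` and ``co2_pct``.  Run configurations are a
single structured text file (YAML, of which JSON is a subset); unknown keys
are rejected before any simulation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maneuver import BreathManeuver, Expirogram
from .morphometry import AnatomicalConstants
from .physiology import ExchangeParams, TissueBloodParams
from .solver import NumericsConfig

__all__ = [
    "ConfigError",
    "ParseError",
    "read_expirogram_csv",
    "write_expirogram_csv",
    "SensorModel",
    "RunConfig",
    "load_config",
]

REQUIRED_COLUMNS = ("time_s", "co_ppb")
KNOWN_COLUMNS = ("time_s", "volume_ml", "co_ppb", "flow_ml_s", "co2_pct")


class ConfigError(ValueError):
    """Invalid run configuration."""


class ParseError(ValueError):
    """Malformed expirogram file."""


def read_expirogram_csv(path) -> Expirogram:
    """Read an expirogram from delimited text.

    Requires ``time_s`` and ``co_ppb`` columns; ``volume_ml`` is integrated
    from ``flow_ml_s`` when absent.  Non-monotone times are reported with the
    offending line number (1-based, counting the header).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if "volume_ml" not in df.columns and "flow_ml_s" not in df.columns:
        raise ParseError(f"{path}: need either volume_ml or flow_ml_s")
    t = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        line = int(bad[0]) + 3  # header + 1-based + offending second row
        raise ParseError(f"{path}: non-monotone time_s at line {line}")
    if not np.all(np.isfinite(df[list(set(df.columns) & set(KNOWN_COLUMNS))])):
        raise ParseError(f"{path}: non-finite values present")
    if "volume_ml" in df.columns:
        volume = df["volume_ml"].to_numpy(float)
    else:
        flow = df["flow_ml_s"].to_numpy(float)
        volume = np.concatenate(([0.0], np.cumsum(0.5 * (flow[1:] + flow[:-1]) * np.diff(t))))
        if volume[0] == 0.0:  # keep strictly increasing
            volume = volume + np.arange(volume.size) * 1e-12
    metadata = {}
    if "co2_pct" in df.columns:
        metadata["et_co2_pct"] = float(df["co2_pct"].iloc[-1])
    return Expirogram(
        time_s=t,
        volume_ml=volume,
        co_ppb=df["co_ppb"].to_numpy(float),
        flow_ml_s=df["flow_ml_s"].to_numpy(float) if "flow_ml_s" in df.columns else None,
        metadata=metadata,
    )


def write_expirogram_csv(expirogram: Expirogram, path) -> None:
    """Write an expirogram as delimited text (lossless round trip)."""
    df = expirogram.to_dataframe()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


@dataclass(frozen=True)
class SensorModel:
    """Characteristics of the real-time CO sensor emulated by the synthetic
    data generator: sampling interval 0.14 s with ~2 ppb precision, plus
    optional flow jitter and start/end flow ramps of the breath sampler."""

    sampling_interval_s: float = 0.14
    noise_sd_ppb: float = 2.0
    flow_jitter_sd_ml_s: float = 0.0
    flow_ramp_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sampling_interval_s", "noise_sd_ppb",
                     "flow_jitter_sd_ml_s", "flow_ramp_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.sampling_interval_s == 0:
            raise ConfigError("sampling_interval_s must be positive")


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")
    coerced = {}
    for key, value in section.items():
        if isinstance(value, str):
            # YAML 1.1 reads exponent literals without a sign ("1.76e7")
            # as strings; accept them as numbers
            try:
                value = float(value)
            except ValueError:
                raise ConfigError(
                    f"invalid value for {name}.{key}: {value!r}"
                ) from None
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name!r} section: {exc}") from exc


@dataclass
class RunConfig:
    """Fully validated run configuration."""

    anatomy: AnatomicalConstants = field(default_factory=AnatomicalConstants)
    tissue_blood: TissueBloodParams | None = None
    exchange: ExchangeParams | None = None
    maneuver: BreathManeuver | None = None
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    sensor: SensorModel = field(default_factory=SensorModel)
    species: str = "co"
    seed: int | None = None
    generation_table: str | None = None

    TOP_LEVEL = ("anatomy", "tissue_blood", "exchange", "maneuver", "numerics",
                 "sensor", "species", "seed", "generation_table")


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON configuration file.

    Unknown keys anywhere raise :class:`ConfigError`; nothing is simulated
    before the whole file validates.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - set(RunConfig.TOP_LEVEL)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    species = raw.get("species", "co")
    if species not in ("co", "no"):
        raise ConfigError(f"species must be 'co' or 'no', got {species!r}")
    cfg = RunConfig(species=species)
    if "anatomy" in raw:
        cfg.anatomy = _build(AnatomicalConstants, raw["anatomy"], "anatomy")
    if "tissue_blood" in raw:
        cfg.tissue_blood = _build(TissueBloodParams, raw["tissue_blood"], "tissue_blood")
    if "exchange" in raw:
        cfg.exchange = _build(ExchangeParams, raw["exchange"], "exchange")
    if "maneuver" in raw:
        cfg.maneuver = _build(BreathManeuver, raw["maneuver"], "maneuver")
    if "numerics" in raw:
        cfg.numerics = _build(NumericsConfig, raw["numerics"], "numerics")
    if "sensor" in raw:
        cfg.sensor = _build(SensorModel, raw["sensor"], "sensor")
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "generation_table" in raw:
        cfg.generation_table = str(raw["generation_table"])
    return cfg
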