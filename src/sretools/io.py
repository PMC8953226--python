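"""Config handling and validated delimited-text I/O.

All exchange files are comma-separated UTF-8 with "." decimals; column
names carry unit suffixes (``_s``, ``_umol_L``, ``_g_L``, ...) that are
asserted on read.  Configuration is TOML with the sections
[reactor], [feed], [kinetics], [gas], [sensors], [metabolome], [synth];
unknown sections or keys are rejected so typos cannot silently fall back
to defaults.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .offgas import SensorModel
from .reactor import FeedSchedule, KineticParams, ReactorParams

logger = logging.getLogger("sretools")


def configure_logging(level: int = logging.INFO) -> None:
    """Route package logs to standard error with a compact format."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


class SchemaError(ValueError):
    """A delimited-text file does not match its expected schema."""


class ConfigError(ValueError):
    """A configuration file contains unknown or invalid entries."""


# ---------------------------------------------------------------------------
# Time-series I/O
# ---------------------------------------------------------------------------

def read_timeseries(path, columns: tuple[str, ...],
                    time_column: str | None = None) -> pd.DataFrame:
    """Read a delimited time series and validate its schema.

    ``columns`` are the required column names; names double as the unit
    contract (e.g. ``glucose_umol_L``), so a renamed or re-united column is
    a schema error naming the column.  The time column (default: the first
    required column) must be strictly increasing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})")
    tcol = time_column or columns[0]
    t = df[tcol].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise SchemaError(f"{path.name}: column {tcol} must be strictly increasing")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a report table as CSV (header always present, even if empty)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    reactor: ReactorParams = field(default_factory=ReactorParams)
    feed: FeedSchedule = field(default_factory=lambda: FeedSchedule(
        mode="intermittent", cycle_period=9.0, off_duration=2.0, on_rate=3.64))
    kinetics: KineticParams = field(default_factory=KineticParams)
    gas: dict = field(default_factory=lambda: {
        "inlet_o2": 0.2095, "inlet_co2": 0.0004, "flow_NL_min": 0.8})
    sensors: dict = field(default_factory=lambda: {
        "o2": SensorModel(delay=120.0, time_constant=55.0),
        "co2": SensorModel(delay=120.0, time_constant=55.0)})
    metabolome: dict = field(default_factory=lambda: {
        "include": None, "exclude": ["PYR"], "mds_dimensions": 2})
    synth: dict = field(default_factory=dict)


_SECTION_FIELDS = {
    "reactor": {"working_volume", "feed_glucose", "base_feed_rate", "gas_flow_in"},
    "feed": {"mode", "cycle_period", "off_duration", "on_rate"},
    "kinetics": {"q_max", "K_M", "yield_xs", "maintenance_q",
                 "overflow_threshold", "starvation_threshold"},
    "gas": {"inlet_o2", "inlet_co2", "flow_NL_min"},
    "sensors": {"o2_delay", "o2_time_constant", "co2_delay", "co2_time_constant"},
    "metabolome": {"include", "exclude", "mds_dimensions"},
    "synth": {"seed", "replicates", "n_cycles", "ref_duration_h", "recovery_min",
              "gas_noise_sd", "metabolite_noise_sd"},
}


def read_config(path) -> PipelineConfig:
    """Load a TOML config, rejecting unknown sections and keys."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - set(_SECTION_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")
    for section, entries in raw.items():
        bad = set(entries) - _SECTION_FIELDS[section]
        if bad:
            raise ConfigError(
                f"unknown key(s) in [{section}]: {', '.join(sorted(bad))}")

    cfg = PipelineConfig()
    if "reactor" in raw:
        cfg.reactor = ReactorParams(**{**dataclasses.asdict(cfg.reactor), **raw["reactor"]})
    if "feed" in raw:
        cfg.feed = FeedSchedule(**{**dataclasses.asdict(cfg.feed), **raw["feed"]})
    if "kinetics" in raw:
        cfg.kinetics = KineticParams(**{**dataclasses.asdict(cfg.kinetics), **raw["kinetics"]})
    if "gas" in raw:
        cfg.gas.update(raw["gas"])
    if "sensors" in raw:
        s = raw["sensors"]
        cfg.sensors = {
            "o2": SensorModel(
                delay=s.get("o2_delay", cfg.sensors["o2"].delay),
                time_constant=s.get("o2_time_constant", cfg.sensors["o2"].time_constant)),
            "co2": SensorModel(
                delay=s.get("co2_delay", cfg.sensors["co2"].delay),
                time_constant=s.get("co2_time_constant", cfg.sensors["co2"].time_constant)),
        }
    if "metabolome" in raw:
        cfg.metabolome.update(raw["metabolome"])
    if "synth" in raw:
        cfg.synth.update(raw["synth"])
    logger.debug("resolved config: %s", cfg)
    return cfg
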