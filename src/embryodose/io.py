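"""Run configuration parsing and result serialization.

Configs are YAML (JSON is a YAML subset, so either works on disk).  Unknown
keys are rejected rather than ignored -- a typo in a physical parameter
must not silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .kinematics import Placement
from .medium import (
    Calibration,
    MediumProperties,
    SourceSpec,
    agar_block,
    WATER_D_CM2_S,
    WATER_SIGMA_D_CM2_S,
)

__all__ = ["RunConfig", "ConfigError", "parse_config", "write_profiles", "read_profiles"]

log = logging.getLogger("embryodose")


class ConfigError(ValueError):
    """Raised for missing, unknown or non-physical configuration values."""


_MEDIUM_KEYS = {"D", "sigma_D", "lam", "R"}
_PLACEMENT_KEYS = {"class", "distance_mm", "lateral_mm"}
_GRID_KEYS = {"start_h", "end_h", "step_h"}
_TOP_KEYS = {
    "drug",
    "series",
    "soak_volume_ul",
    "soak_molarity_M",
    "block_mm",
    "placement",
    "medium",
    "calibration",
    "t_grid",
    "seed",
}

_DRUG_DEFAULTS = {
    "AT": {"soak_volume_ul": 3.0, "soak_molarity_M": 1e-3},
    "CCh": {"soak_volume_ul": 2.0, "soak_molarity_M": 0.1},
    "control": {"soak_volume_ul": 3.0, "soak_molarity_M": 0.0},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted description of one exposure run."""

    drug: str
    placement: Placement
    series: str = "EA"
    soak_volume_ul: float = 3.0
    soak_molarity_M: float = 1e-3
    block_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    medium: MediumProperties = field(
        default_factory=lambda: MediumProperties.isotropic(
            WATER_D_CM2_S, WATER_SIGMA_D_CM2_S
        )
    )
    calibration: Calibration = Calibration.VOLUMETRIC
    t_start_h: float = 0.0
    t_end_h: float = 30.0
    t_step_h: float = 0.1
    seed: int = 0

    def source(self) -> SourceSpec:
        return agar_block(
            self.block_mm, self.soak_volume_ul, self.soak_molarity_M, self.calibration
        )

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "series": self.series,
            "soak_volume_ul": self.soak_volume_ul,
            "soak_molarity_M": self.soak_molarity_M,
            "block_mm": list(self.block_mm),
            "placement": {
                "class": self.placement.klass,
                "distance_mm": self.placement.distance_mm,
                "lateral_mm": self.placement.lateral_mm,
            },
            "medium": {
                "D": self.medium.Dx,
                "sigma_D": self.medium.sigma_D,
                "lam": self.medium.lam,
                "R": self.medium.R,
            },
            "calibration": self.calibration.value,
            "t_grid": {
                "start_h": self.t_start_h,
                "end_h": self.t_end_h,
                "step_h": self.t_step_h,
            },
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _reject_unknown(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")


def parse_config(path_or_mapping) -> RunConfig:
    """Parse and validate a run configuration from a YAML/JSON file or dict.

    A minimal config needs only ``drug`` and ``placement``; everything else
    defaults to the standard experiment (2x2x3 mm agar block, the drug's
    standard soak, D = 6e-6 +- 3e-6 cm^2/s, no decay, no sorption).
    """
    if isinstance(path_or_mapping, dict):
        raw = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    for key in ("drug", "placement"):
        if key not in raw:
            raise ConfigError(f"missing required key: {key!r}")
    drug = str(raw["drug"])
    if drug not in _DRUG_DEFAULTS:
        raise ConfigError(f"unknown drug {drug!r}; expected one of {list(_DRUG_DEFAULTS)}")

    pl = dict(raw["placement"])
    _reject_unknown(pl, _PLACEMENT_KEYS, "placement")
    if "class" not in pl or "distance_mm" not in pl:
        raise ConfigError("placement needs 'class' and 'distance_mm'")
    try:
        placement = Placement(
            klass=str(pl["class"]),
            distance_mm=float(pl["distance_mm"]),
            lateral_mm=float(pl.get("lateral_mm", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    med_raw = dict(raw.get("medium", {}))
    _reject_unknown(med_raw, _MEDIUM_KEYS, "medium")
    try:
        medium = MediumProperties.isotropic(
            D=float(med_raw.get("D", WATER_D_CM2_S)),
            sigma_D=float(med_raw.get("sigma_D", WATER_SIGMA_D_CM2_S)),
            lam=float(med_raw.get("lam", 0.0)),
            R=float(med_raw.get("R", 1.0)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    grid_raw = dict(raw.get("t_grid", {}))
    _reject_unknown(grid_raw, _GRID_KEYS, "t_grid")
    series = str(raw.get("series", "EA"))
    if series not in ("EA", "EB"):
        raise ConfigError(f"unknown series {series!r}")
    default_end = 30.0 if series == "EA" else 9.0
    t_start = float(grid_raw.get("start_h", 0.0))
    t_end = float(grid_raw.get("end_h", default_end))
    t_step = float(grid_raw.get("step_h", 0.1))
    if t_start < 0 or t_end <= t_start or t_step <= 0:
        raise ConfigError("t_grid must satisfy 0 <= start < end, step > 0")

    defaults = _DRUG_DEFAULTS[drug]
    soak_volume = float(raw.get("soak_volume_ul", defaults["soak_volume_ul"]))
    soak_molarity = float(raw.get("soak_molarity_M", defaults["soak_molarity_M"]))
    if soak_volume < 0 or soak_molarity < 0:
        raise ConfigError("soak volume and molarity must be >= 0")
    block = tuple(float(v) for v in raw.get("block_mm", (2.0, 2.0, 3.0)))
    if len(block) != 3 or any(v <= 0 for v in block):
        raise ConfigError("block_mm must be three positive lengths")
    try:
        calibration = Calibration(raw.get("calibration", "volumetric"))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    cfg = RunConfig(
        drug=drug,
        placement=placement,
        series=series,
        soak_volume_ul=soak_volume,
        soak_molarity_M=soak_molarity,
        block_mm=block,  # type: ignore[arg-type]
        medium=medium,
        calibration=calibration,
        t_start_h=t_start,
        t_end_h=t_end,
        t_step_h=t_step,
        seed=int(raw.get("seed", 0)),
    )
    log.info("parsed config %s (seed=%d)", cfg.config_hash(), cfg.seed)
    return cfg


#: Profile CSV layout: scientific notation, 6 significant digits.
_PROFILE_COLUMNS = ["time_h", "x_mm", "y_mm", "conc_M", "conc_lo_M", "conc_hi_M"]
_FLOAT_FORMAT = "%.5e"


def write_profiles(table: pd.DataFrame, path) -> Path:
    """Write a concentration-profile table to CSV (6 significant digits)."""
    if table.empty:
        raise ValueError("profile table is empty")
    missing = [c for c in _PROFILE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"profile table missing columns: {missing}")
    path = Path(path)
    table[_PROFILE_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)
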