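"""Synthetic atlas of homogeneous territorial units.

Real applications of this modelling chain intersect GIS layers (thermal
zone, land cover, soil type/texture, country) into homogeneous units and
attach climate normals, clay content and an initial SOC stock to each.
This module emulates that product statistically: units are drawn from
four thermal zones with zone-consistent seasonal climate, bounded soil
properties, independent normal per-variable uncertainty, and a
per-class biophysical feasibility mask.  Everything is deterministic
given the configuration seed, so downstream stages are testable without
any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .carbon_inputs import LandUseSpec
from .forcing import DAYS_IN_MONTH, ClimateNormals
from .rothc import SoilProfile

__all__ = [
    "THERMAL_ZONES",
    "ConfigError",
    "SyntheticAtlasConfig",
    "UHTURecord",
    "day_length_hours",
    "generate_uhtus",
    "generate_feasibility",
    "uhtus_to_frame",
    "frame_to_uhtus",
    "save_atlas",
    "load_atlas",
]

THERMAL_ZONES = ("boreal", "temperate", "subtropical", "tropical")

#: Zone climate envelopes: annual-mean temperature range (degC), seasonal
#: amplitude range (degC), annual precipitation range (mm), and the
#: representative latitude band (deg) used for day length.
_ZONE_CLIMATE = {
    "boreal": {"t_ann": (-6.0, 2.0), "t_amp": (10.0, 16.0),
               "p_ann": (350.0, 750.0), "lat": 60.0},
    "temperate": {"t_ann": (7.0, 13.0), "t_amp": (8.0, 14.0),
                  "p_ann": (450.0, 1000.0), "lat": 45.0},
    "subtropical": {"t_ann": (16.0, 22.0), "t_amp": (4.0, 8.0),
                    "p_ann": (300.0, 1100.0), "lat": 30.0},
    "tropical": {"t_ann": (24.0, 28.0), "t_amp": (1.0, 3.0),
                 "p_ann": (800.0, 2200.0), "lat": 10.0},
}

#: Probability that a given crop is biophysically feasible in a unit of
#: each zone (forest classes are tied to their zone; grassland is
#: feasible everywhere).
_CROP_FEASIBILITY_P = {
    "boreal": 0.25,
    "temperate": 0.60,
    "subtropical": 0.55,
    "tropical": 0.50,
}


class ConfigError(ValueError):
    """Invalid synthetic-atlas configuration."""


def day_length_hours(latitude_deg: float) -> np.ndarray:
    """Mean day length (h) per month at a latitude, from solar geometry."""
    phi = math.radians(latitude_deg)
    mid_doy = np.cumsum(DAYS_IN_MONTH) - DAYS_IN_MONTH / 2.0
    decl = np.radians(-23.44) * np.cos(2.0 * np.pi * (mid_doy + 10.0) / 365.0)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_omega)


@dataclass
class SyntheticAtlasConfig:
    """Parameters of the synthetic atlas generator."""

    n_uhtus: int = 50
    seed: int = 0
    thermal_zone_mix: dict = field(
        default_factory=lambda: {
            "boreal": 0.20, "temperate": 0.30,
            "subtropical": 0.25, "tropical": 0.25,
        }
    )
    clay_range: tuple = (8.0, 45.0)
    soc0_range: tuple = (25.0, 120.0)
    relative_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.n_uhtus < 1:
            raise ConfigError("n_uhtus must be >= 1")
        if set(self.thermal_zone_mix) - set(THERMAL_ZONES):
            raise ConfigError("unknown thermal zone in mix")
        if abs(sum(self.thermal_zone_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("thermal zone proportions must sum to 1")
        if any(p < 0 for p in self.thermal_zone_mix.values()):
            raise ConfigError("thermal zone proportions must be non-negative")
        for name in ("clay_range", "soc0_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name} must be ordered (min, max)")
        if not 0.0 <= self.clay_range[0] or not self.clay_range[1] <= 100.0:
            raise ConfigError("clay_range must lie within [0, 100] %")
        if self.soc0_range[0] <= 0.0:
            raise ConfigError("soc0_range must be positive")
        if self.relative_sd < 0.0:
            raise ConfigError("relative_sd must be non-negative")

    def to_yaml(self, path) -> None:
        data = {
            "n_uhtus": int(self.n_uhtus),
            "seed": int(self.seed),
            "thermal_zone_mix": {k: float(v) for k, v in self.thermal_zone_mix.items()},
            "clay_range": [float(x) for x in self.clay_range],
            "soc0_range": [float(x) for x in self.soc0_range],
            "relative_sd": float(self.relative_sd),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticAtlasConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["clay_range"] = tuple(data["clay_range"])
        data["soc0_range"] = tuple(data["soc0_range"])
        return cls(**data)


@dataclass
class UHTURecord:
    """One homogeneous territorial unit."""

    uhtu_id: str
    thermal_zone: str
    latitude_band: float
    climate: ClimateNormals
    soil: SoilProfile
    clay_sd: float
    soc0_sd: float
    feasible_classes: set = field(default_factory=set)


def generate_uhtus(config: SyntheticAtlasConfig) -> list:
    """Draw a deterministic set of territorial units from the config.

    Zone membership follows the configured mix; monthly temperature is a
    seasonal cosine around a zone-consistent annual mean (northern-
    hemisphere phase, July warmest), precipitation a mildly seasonal
    split of the annual total, and clay / initial SOC uniform draws
    within the configured ranges.  Each variable's standard deviation is
    ``relative_sd`` times the absolute value of its mean.
    """
    rng = np.random.default_rng(config.seed)
    zones = list(THERMAL_ZONES)
    probs = np.array([config.thermal_zone_mix.get(z, 0.0) for z in zones])
    months = np.arange(12)
    records = []
    for i in range(config.n_uhtus):
        zone = zones[rng.choice(len(zones), p=probs)]
        env = _ZONE_CLIMATE[zone]
        t_ann = rng.uniform(*env["t_ann"])
        t_amp = rng.uniform(*env["t_amp"])
        p_ann = rng.uniform(*env["p_ann"])
        p_season = rng.uniform(0.2, 0.6)
        p_peak = rng.integers(0, 12)
        temp = t_ann + t_amp * np.cos(2.0 * np.pi * (months - 6) / 12.0)
        precip = p_ann / 12.0 * (
            1.0 + p_season * np.cos(2.0 * np.pi * (months - p_peak) / 12.0)
        )
        clay = rng.uniform(*config.clay_range)
        soc0 = rng.uniform(*config.soc0_range)
        lat = env["lat"]
        climate = ClimateNormals(
            temp_mean=temp,
            temp_sd=config.relative_sd * np.abs(temp),
            precip_mean=precip,
            precip_sd=config.relative_sd * precip,
            day_length=day_length_hours(lat),
        )
        records.append(
            UHTURecord(
                uhtu_id=f"uhtu{i:05d}",
                thermal_zone=zone,
                latitude_band=lat,
                climate=climate,
                soil=SoilProfile(clay=clay, soc0=soc0),
                clay_sd=config.relative_sd * clay,
                soc0_sd=config.relative_sd * soc0,
            )
        )
    return records


def generate_feasibility(uhtus: Sequence[UHTURecord], registry: dict,
                         seed: int = 0) -> Sequence[UHTURecord]:
    """Assign feasible land-use classes to each unit (in place).

    Grassland classes are always feasible; forest classes only in their
    matching thermal zone; each crop is feasible with a zone-dependent
    probability, and feasibility applies to all management variants of
    the crop at once.
    """
    if not registry:
        raise ValueError("empty land-use class registry")
    rng = np.random.default_rng(seed)
    by_crop: dict[str, list[str]] = {}
    grass_ids, forest = [], []
    for cid, cls in registry.items():
        spec: LandUseSpec = cls.spec
        if spec.broad_type == "grassland":
            grass_ids.append(cid)
        elif spec.broad_type == "forest":
            forest.append((cid, spec.thermal_zone))
        else:
            by_crop.setdefault(spec.crop, []).append(cid)
    crops = sorted(by_crop)
    for rec in uhtus:
        feasible = set(grass_ids)
        feasible.update(cid for cid, zone in forest if zone == rec.thermal_zone)
        p = _CROP_FEASIBILITY_P[rec.thermal_zone]
        draws = rng.random(len(crops))
        for crop, u in zip(crops, draws):
            if u < p:
                feasible.update(by_crop[crop])
        rec.feasible_classes = feasible
    return uhtus


# ---------------------------------------------------------------------------
# tabular serialization

def uhtus_to_frame(uhtus: Sequence[UHTURecord]) -> pd.DataFrame:
    rows = []
    for rec in uhtus:
        row = {
            "uhtu_id": rec.uhtu_id,
            "thermal_zone": rec.thermal_zone,
            "latitude_band": rec.latitude_band,
            "clay": float(np.asarray(rec.soil.clay)),
            "clay_sd": rec.clay_sd,
            "soc0": float(np.asarray(rec.soil.soc0)),
            "soc0_sd": rec.soc0_sd,
            "depth_cm": rec.soil.depth,
            "feasible_classes": ";".join(sorted(rec.feasible_classes)),
        }
        for m in range(12):
            row[f"temp_mean_{m+1:02d}"] = rec.climate.temp_mean[m]
            row[f"temp_sd_{m+1:02d}"] = rec.climate.temp_sd[m]
            row[f"precip_mean_{m+1:02d}"] = rec.climate.precip_mean[m]
            row[f"precip_sd_{m+1:02d}"] = rec.climate.precip_sd[m]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_uhtus(frame: pd.DataFrame) -> list:
    records = []
    for _, row in frame.iterrows():
        climate = ClimateNormals(
            temp_mean=np.array([row[f"temp_mean_{m+1:02d}"] for m in range(12)]),
            temp_sd=np.array([row[f"temp_sd_{m+1:02d}"] for m in range(12)]),
            precip_mean=np.array([row[f"precip_mean_{m+1:02d}"] for m in range(12)]),
            precip_sd=np.array([row[f"precip_sd_{m+1:02d}"] for m in range(12)]),
            day_length=day_length_hours(float(row["latitude_band"])),
        )
        feas = row.get("feasible_classes", "")
        feasible = set(str(feas).split(";")) if isinstance(feas, str) and feas else set()
        records.append(
            UHTURecord(
                uhtu_id=str(row["uhtu_id"]),
                thermal_zone=str(row["thermal_zone"]),
                latitude_band=float(row["latitude_band"]),
                climate=climate,
                soil=SoilProfile(
                    clay=float(row["clay"]),
                    soc0=float(row["soc0"]),
                    depth=float(row.get("depth_cm", 30.0)),
                ),
                clay_sd=float(row["clay_sd"]),
                soc0_sd=float(row["soc0_sd"]),
                feasible_classes=feasible,
            )
        )
    return records


def save_atlas(uhtus: Sequence[UHTURecord], path) -> None:
    uhtus_to_frame(uhtus).to_csv(path, index=False)


def load_atlas(path) -> list:
    return frame_to_uhtus(pd.read_csv(path))
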