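"""Monthly carbon-input and soil-cover schedules per land-use class.

Annual crop residue carbon is an IPCC-style linear function of yield:
above-ground residue dry matter is ``slope * yield + intercept`` and
below-ground residue a fixed fraction of total above-ground mass.  Annual
totals are then spread over the months: cereals (and other annual crops)
put 50 % into the harvest month and the rest equally into the three
months before; permanent crops put 70 % into the pruning month and the
rest equally into the four months before; forests and grasslands shed
litter uniformly.  Farmyard manure is derived from fertilizer nitrogen by
scenario fraction and a fixed C:N ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CARBON_CONTENT",
    "MANURE_C_TO_N",
    "LandUseSpec",
    "ManagementSpec",
    "CarbonInputSchedule",
    "annual_crop_residue_c",
    "distribute_monthly",
    "manure_c",
    "grazing_dung_c",
    "forest_litter_schedule",
    "soil_cover_flags",
]

#: Carbon content of plant residues, kg C per kg dry matter.
CARBON_CONTENT = 0.40

#: C:N mass ratio of farmyard manure, kg C per kg N.
MANURE_C_TO_N = 14.0

_BROAD_TYPES = ("cropland", "grassland", "forest")
_MANURE_SCENARIOS = (0.0, 0.5, 1.0)


def _check_month(name: str, m: Optional[int], required: bool = False) -> None:
    if m is None:
        if required:
            raise ValueError(f"{name} is required for this land-use type")
        return
    if not 1 <= int(m) <= 12:
        raise ValueError(f"{name} must be a month index in 1..12")


@dataclass
class LandUseSpec:
    """One land-use class: calendar, residue and litter parameters.

    Only the fields relevant to ``broad_type`` are populated; e.g. forest
    classes carry litter parameters and a thermal zone, cropland classes a
    crop calendar and residue coefficients.
    """

    class_id: str
    broad_type: str
    crop: Optional[str] = None
    is_cereal: bool = False
    is_permanent: bool = False
    sowing_month: Optional[int] = None
    harvest_month: Optional[int] = None
    pruning_month: Optional[int] = None
    dpm_rpm_ratio: float = 1.44
    yield_mean: Optional[float] = None  # t DM/ha/yr
    yield_sd: float = 0.0
    ag_slope: float = 0.0
    ag_intercept: float = 0.0
    bg_ratio: float = 0.0
    forest_litter_mature: Optional[float] = None  # t C/ha/yr
    forest_maturity_years: Optional[int] = None
    thermal_zone: Optional[str] = None  # forest classes only
    kc_profile: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.broad_type not in _BROAD_TYPES:
            raise ValueError(f"unknown broad_type {self.broad_type!r}")
        if self.dpm_rpm_ratio <= 0.0:
            raise ValueError("dpm_rpm_ratio must be positive")
        _check_month("sowing_month", self.sowing_month)
        _check_month("harvest_month", self.harvest_month)
        _check_month("pruning_month", self.pruning_month)
        if self.broad_type == "forest":
            if self.forest_litter_mature is None or self.forest_maturity_years is None:
                raise ValueError("forest classes need litter and maturity parameters")
            if self.forest_maturity_years < 1:
                raise ValueError("forest_maturity_years must be >= 1")
        if self.is_cereal and self.is_permanent:
            raise ValueError("a class cannot be both cereal and permanent")
        if self.kc_profile is not None:
            self.kc_profile = np.asarray(self.kc_profile, dtype=float)
            if self.kc_profile.shape != (12,):
                raise ValueError("kc_profile must have 12 monthly values")
            if np.any(self.kc_profile < 0.0):
                raise ValueError("kc_profile must be non-negative")


@dataclass(frozen=True)
class ManagementSpec:
    """Management options: irrigation, cereal residue fate, manure scenario.

    ``manure_scenario`` is the fraction of fertilizer nitrogen applied as
    farmyard manure (0, 0.5 or 1).
    """

    irrigated: bool = False
    residues_left: Optional[bool] = None
    manure_scenario: float = 0.0

    def __post_init__(self) -> None:
        if self.manure_scenario not in _MANURE_SCENARIOS:
            raise ValueError("manure_scenario must be one of 0, 0.5, 1")


@dataclass
class CarbonInputSchedule:
    """Monthly plant and manure carbon inputs plus soil-cover flags."""

    plant_c: np.ndarray  # t C/ha per month, leading dims broadcast
    fym_c: np.ndarray
    cover: np.ndarray  # binary, (12,)

    def __post_init__(self) -> None:
        self.plant_c = np.asarray(self.plant_c, dtype=float)
        self.fym_c = np.asarray(self.fym_c, dtype=float)
        self.cover = np.asarray(self.cover)
        if np.any(self.plant_c < 0.0) or np.any(self.fym_c < 0.0):
            raise ValueError("carbon inputs must be non-negative")
        if not np.all(np.isin(self.cover, (0, 1))):
            raise ValueError("cover flags must be binary")


def annual_crop_residue_c(yield_dm, spec: LandUseSpec, residues_left: bool,
                          carbon_content: float = CARBON_CONTENT):
    """Annual residue carbon input (t C/ha/yr) from yield dry matter.

    above = ag_slope * yield + ag_intercept
    below = bg_ratio * (yield + above)
    residue C = carbon_content * (below + above if residues are left,
    below only if they are removed).
    """
    y = np.asarray(yield_dm, dtype=float)
    if np.any(y < 0.0):
        raise ValueError("yield must be non-negative")
    above = spec.ag_slope * y + spec.ag_intercept
    below = spec.bg_ratio * (y + above)
    if residues_left:
        return carbon_content * (below + above)
    return carbon_content * below


def distribute_monthly(annual_c, spec: LandUseSpec) -> np.ndarray:
    """Spread an annual carbon input over the 12 months of a year.

    Permanent crops: 70 % in the pruning month, 30 % equally over the four
    months before.  Other croplands: 50 % in the harvest month, 50 %
    equally over the three months before.  Forests and grasslands:
    uniform.  Month arithmetic wraps across the year boundary.
    """
    annual = np.asarray(annual_c, dtype=float)
    if np.any(annual < 0.0):
        raise ValueError("annual carbon input must be non-negative")
    weights = np.zeros(12)
    if spec.broad_type in ("forest", "grassland"):
        weights[:] = 1.0 / 12.0
    elif spec.is_permanent:
        if spec.pruning_month is None:
            raise ValueError("permanent crop without a pruning month")
        pm = int(spec.pruning_month) - 1
        weights[pm] = 0.70
        for back in range(1, 5):
            weights[(pm - back) % 12] = 0.30 / 4.0
    else:
        if spec.harvest_month is None:
            raise ValueError("annual crop without a harvest month")
        hm = int(spec.harvest_month) - 1
        weights[hm] = 0.50
        for back in range(1, 4):
            weights[(hm - back) % 12] = 0.50 / 3.0
    return annual[..., np.newaxis] * weights


def manure_c(total_n, scenario_fraction: float, c_to_n: float = MANURE_C_TO_N):
    """Annual manure carbon from fertilizer nitrogen (t C/ha/yr).

    ``scenario_fraction`` of the nitrogen is applied as farmyard manure
    and converted to carbon by the manure C:N ratio.
    """
    n = np.asarray(total_n, dtype=float)
    if np.any(n < 0.0):
        raise ValueError("nitrogen input must be non-negative")
    if c_to_n <= 0.0:
        raise ValueError("C:N ratio must be positive")
    if scenario_fraction not in _MANURE_SCENARIOS:
        raise ValueError("manure scenario must be one of 0, 0.5, 1")
    return scenario_fraction * n * c_to_n


def grazing_dung_c(stocking, excretion_c):
    """Annual dung carbon on grassland: livestock units x excretion rate."""
    s = np.asarray(stocking, dtype=float)
    e = np.asarray(excretion_c, dtype=float)
    if np.any(s < 0.0) or np.any(e < 0.0):
        raise ValueError("stocking and excretion must be non-negative")
    return s * e


def forest_litter_schedule(spec: LandUseSpec, years: int) -> np.ndarray:
    """Annual forest litter inputs (t C/ha/yr) for years 1..years.

    Litter ramps linearly from zero to the mature rate over the maturity
    period and stays constant after.
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if spec.forest_litter_mature is None or spec.forest_maturity_years is None:
        raise ValueError("not a forest class")
    y = np.arange(1, years + 1, dtype=float)
    return spec.forest_litter_mature * np.minimum(1.0, y / spec.forest_maturity_years)


def soil_cover_flags(spec: LandUseSpec, mgmt: ManagementSpec) -> np.ndarray:
    """Monthly binary soil-cover flags.

    Permanent crops, forests and grasslands are covered all year, as are
    cereals whose residues are left on the field.  Other annual crops are
    covered from sowing to harvest inclusive (wrapping) and bare outside.
    """
    if spec.broad_type in ("forest", "grassland") or spec.is_permanent:
        return np.ones(12, dtype=int)
    if spec.is_cereal and mgmt.residues_left:
        return np.ones(12, dtype=int)
    if spec.sowing_month is None or spec.harvest_month is None:
        raise ValueError("annual crop without a sowing/harvest calendar")
    cover = np.zeros(12, dtype=int)
    m = int(spec.sowing_month) - 1
    end = int(spec.harvest_month) - 1
    while True:
        cover[m] = 1
        if m == end:
            break
        m = (m + 1) % 12
    return cover
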