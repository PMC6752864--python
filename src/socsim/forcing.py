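"""Monthly water and evaporation forcing.

Potential evapotranspiration follows the Thornthwaite (1948) formulation:
an annual heat index accumulated from the monthly mean temperatures, a
cubic exponent in that index, and a correction for day length and month
length.  Open-pan evaporation (the water-loss driver of the turnover
kernel) is taken as 75 % of PET.  Crop water requirement is the product
of a monthly crop coefficient (kc) and PET; irrigation demand is the
positive part of requirement minus precipitation, so irrigated schedules
always receive at least the rainfed water input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_IN_MONTH",
    "ClimateNormals",
    "WaterSchedule",
    "thornthwaite_pet",
    "open_pan_evaporation",
    "crop_water_requirement",
    "irrigation_demand",
    "make_water_schedule",
]

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

#: Above this temperature (degC) the high-temperature PET branch applies.
_HIGH_T = 26.5
#: The high-temperature quadratic is evaluated at no more than 38 degC.
_HIGH_T_CAP = 38.0


def _require_12(name: str, arr: np.ndarray) -> None:
    if arr.shape[-1] != 12:
        raise ValueError(f"{name} must have 12 monthly entries on the last axis")


@dataclass
class ClimateNormals:
    """Monthly climate normals with per-month uncertainty.

    Temperatures in degC, precipitation in mm, day length in hours.
    """

    temp_mean: np.ndarray
    temp_sd: np.ndarray
    precip_mean: np.ndarray
    precip_sd: np.ndarray
    day_length: np.ndarray
    days_in_month: np.ndarray = None

    def __post_init__(self) -> None:
        if self.days_in_month is None:
            self.days_in_month = DAYS_IN_MONTH.copy()
        for name in ("temp_mean", "temp_sd", "precip_mean", "precip_sd",
                     "day_length", "days_in_month"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (12,):
                raise ValueError(f"{name} must be a length-12 monthly vector")
        if np.any(self.precip_mean < 0.0):
            raise ValueError("precipitation means must be non-negative")
        if np.any(self.temp_sd < 0.0) or np.any(self.precip_sd < 0.0):
            raise ValueError("standard deviations must be non-negative")
        if np.any(self.day_length <= 0.0) or np.any(self.day_length > 24.0):
            raise ValueError("day length must lie in (0, 24] hours")
        if np.any(self.days_in_month < 28) or np.any(self.days_in_month > 31):
            raise ValueError("days per month must lie in [28, 31]")


@dataclass
class WaterSchedule:
    """Derived monthly water forcing for one land use and management."""

    pet: np.ndarray
    open_pan: np.ndarray
    requirement: np.ndarray
    irrigation: np.ndarray
    water_input: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.irrigation < -1e-12):
            raise ValueError("irrigation must be non-negative")
        if not np.allclose(self.open_pan, 0.75 * self.pet):
            raise ValueError("open pan evaporation must equal 0.75 * PET")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": np.arange(1, 13),
                "pet_mm": self.pet,
                "open_pan_mm": self.open_pan,
                "requirement_mm": self.requirement,
                "irrigation_mm": self.irrigation,
                "water_input_mm": self.water_input,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "WaterSchedule":
        return cls(
            pet=frame["pet_mm"].to_numpy(float),
            open_pan=frame["open_pan_mm"].to_numpy(float),
            requirement=frame["requirement_mm"].to_numpy(float),
            irrigation=frame["irrigation_mm"].to_numpy(float),
            water_input=frame["water_input_mm"].to_numpy(float),
        )


def thornthwaite_pet(temps, day_length, days=None):
    """Thornthwaite potential evapotranspiration, mm per month.

    heat index ``I = sum((T/5)**1.514)`` over months with T > 0;
    exponent ``a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239``;
    unadjusted PET ``16 (10 T / I)**a`` for 0 < T < 26.5 degC and the
    standard quadratic high-temperature branch above; each month is then
    scaled by (day length / 12) * (days / 30).  Months at or below 0 degC
    evaporate nothing.

    ``temps`` may carry leading batch dimensions; the last axis must be 12.
    """
    t = np.asarray(temps, dtype=float)
    _require_12("temps", t)
    L = np.asarray(day_length, dtype=float)
    _require_12("day_length", L)
    if days is None:
        days = DAYS_IN_MONTH
    nd = np.asarray(days, dtype=float)
    _require_12("days", nd)

    tp = np.clip(t, 0.0, None)
    heat_index = np.sum((tp / 5.0) ** 1.514, axis=-1, keepdims=True)
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        low = 16.0 * (10.0 * tp / heat_index) ** a
    low = np.where(heat_index > 0.0, low, 0.0)
    th = np.minimum(tp, _HIGH_T_CAP)
    high = -415.85 + 32.24 * th - 0.43 * th * th
    pet_unadj = np.where(tp >= _HIGH_T, high, low)
    pet = np.where(t > 0.0, pet_unadj * (L / 12.0) * (nd / 30.0), 0.0)
    return np.clip(pet, 0.0, None)


def open_pan_evaporation(pet):
    """Open-pan evaporation as 75 % of potential evapotranspiration."""
    pet = np.asarray(pet, dtype=float)
    if np.any(pet < 0.0):
        raise ValueError("PET must be non-negative")
    return 0.75 * pet


def crop_water_requirement(kc, pet):
    """Monthly crop water requirement kc * PET (mm)."""
    kc = np.asarray(kc, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if np.any(kc < 0.0):
        raise ValueError("crop coefficients must be non-negative")
    return kc * pet


def irrigation_demand(requirement, precip):
    """Irrigation as the unmet part of the crop water requirement.

    Zero in months where precipitation covers the requirement, otherwise
    the difference.
    """
    requirement = np.asarray(requirement, dtype=float)
    precip = np.asarray(precip, dtype=float)
    if np.any(requirement < 0.0) or np.any(precip < 0.0):
        raise ValueError("requirement and precipitation must be non-negative")
    return np.maximum(0.0, requirement - precip)


def make_water_schedule(temps, precip, day_length, days=None, kc=None,
                        irrigated: bool = False) -> WaterSchedule:
    """Assemble the full monthly water forcing for one realization.

    Rainfed management (or ``kc=None``) receives precipitation only;
    irrigated management tops precipitation up to the crop requirement.
    """
    pet = thornthwaite_pet(temps, day_length, days)
    pan = open_pan_evaporation(pet)
    if kc is None:
        req = np.zeros_like(pet)
    else:
        req = crop_water_requirement(kc, pet)
    if irrigated:
        irr = irrigation_demand(req, precip)
    else:
        irr = np.zeros_like(pet)
    return WaterSchedule(
        pet=pet,
        open_pan=pan,
        requirement=req,
        irrigation=irr,
        water_input=np.asarray(precip, float) + irr,
    )
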