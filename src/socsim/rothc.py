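"""RothC-26.3 soil carbon turnover kernel.

The Rothamsted carbon model partitions topsoil organic carbon into five
pools: decomposable plant material (DPM), resistant plant material (RPM),
microbial biomass (BIO), humified organic matter (HUM) and inert organic
matter (IOM).  Every pool except IOM decays by first-order kinetics on a
monthly time step; the decay rate of each pool is modulated by three
multiplicative modifiers (temperature, topsoil moisture deficit, soil
cover).  Decomposed carbon is split between respired CO2 and the BIO and
HUM pools, with the CO2 share controlled by clay content.

All kernel functions broadcast over leading array dimensions, so an
ensemble of soil columns can be stepped in one call: a :class:`PoolState`
whose fields are ``(n,)`` arrays behaves as ``n`` independent columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoilProfile",
    "PoolState",
    "RothCParams",
    "temperature_modifier",
    "max_topsoil_moisture_deficit",
    "moisture_modifier_series",
    "co2_partition",
    "initialize_pools",
    "step_month",
    "run_years",
]

#: Temperature rate-modifier constants (dimensionless fit to Rothamsted data).
_TEMP_A = 47.91
_TEMP_B = 106.06
_TEMP_C = 18.27

#: Accumulated deficit below this fraction of the maximum leaves the
#: moisture modifier at 1.
_TSMD_KNEE = 0.444

#: Reference depth (cm) of the maximum-deficit regression.
_TSMD_REF_DEPTH = 23.0

#: Bare soil can only dry out to max deficit / 1.8.
_BARE_DIVISOR = 1.8


@dataclass
class SoilProfile:
    """Topsoil description: clay %, initial SOC stock and profile depth.

    Fields may be scalars or equally shaped arrays (ensemble columns).
    """

    clay: object  # % by mass, 0-100
    soc0: object  # t C/ha in the profile
    depth: float = 30.0  # cm

    def __post_init__(self) -> None:
        clay = np.asarray(self.clay, dtype=float)
        soc0 = np.asarray(self.soc0, dtype=float)
        if np.any(clay < 0.0) or np.any(clay > 100.0):
            raise ValueError("clay content must lie in [0, 100] %")
        if np.any(soc0 <= 0.0):
            raise ValueError("initial SOC stock must be positive")
        if self.depth <= 0.0:
            raise ValueError("profile depth must be positive")


@dataclass
class PoolState:
    """The five RothC carbon pools, t C/ha. Fields broadcast together."""

    dpm: object
    rpm: object
    bio: object
    hum: object
    iom: object

    def total(self):
        return self.dpm + self.rpm + self.bio + self.hum + self.iom

    def as_array(self) -> np.ndarray:
        """Stack pools along a trailing axis, order DPM, RPM, BIO, HUM, IOM."""
        return np.stack(
            np.broadcast_arrays(
                np.asarray(self.dpm, float),
                np.asarray(self.rpm, float),
                np.asarray(self.bio, float),
                np.asarray(self.hum, float),
                np.asarray(self.iom, float),
            ),
            axis=-1,
        )

    @classmethod
    def from_array(cls, arr) -> "PoolState":
        arr = np.asarray(arr, dtype=float)
        return cls(*(arr[..., i] for i in range(5)))

    def validate(self) -> None:
        for name in ("dpm", "rpm", "bio", "hum", "iom"):
            if np.any(np.asarray(getattr(self, name)) < -1e-12):
                raise ValueError(f"negative carbon in pool {name!r}")


@dataclass(frozen=True)
class RothCParams:
    """Kernel constants.

    Decomposition rate constants (1/yr) follow the canonical RothC-26.3
    assignment: DPM 10, RPM 0.3, BIO 0.66, HUM 0.02.  ``fym_split`` is the
    farmyard-manure partition into (DPM, RPM, HUM); ``bio_hum_split`` is
    the destination of non-respired decomposed carbon.
    """

    k_dpm: float = 10.0
    k_rpm: float = 0.3
    k_bio: float = 0.66
    k_hum: float = 0.02
    min_moisture_modifier: float = 0.2
    cover_modifier: float = 0.6
    fym_split: tuple = (0.49, 0.49, 0.02)
    bio_hum_split: tuple = (0.46, 0.54)

    def __post_init__(self) -> None:
        for name in ("k_dpm", "k_rpm", "k_bio", "k_hum"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.min_moisture_modifier <= 1.0:
            raise ValueError("min_moisture_modifier must lie in [0, 1]")
        if abs(sum(self.fym_split) - 1.0) > 1e-9:
            raise ValueError("fym_split must sum to 1")
        if abs(sum(self.bio_hum_split) - 1.0) > 1e-9:
            raise ValueError("bio_hum_split must sum to 1")


DEFAULT_PARAMS = RothCParams()


def temperature_modifier(t):
    """Temperature rate modifier ``a(T)``.

    ``a = 47.91 / (1 + exp(106.06 / (T + 18.27)))`` for T above -18.27 degC,
    zero at and below it.  Strictly increasing, asymptote 47.91/2.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    mask = t > -_TEMP_C
    with np.errstate(over="ignore"):
        out[mask] = _TEMP_A / (1.0 + np.exp(_TEMP_B / (t[mask] + _TEMP_C)))
    return float(out[0]) if scalar else out


def max_topsoil_moisture_deficit(clay, depth: float = 30.0):
    """Maximum topsoil moisture deficit (mm, positive magnitude).

    ``(20.0 + 1.3*clay - 0.01*clay**2) * depth / 23`` -- the Rothamsted
    regression against clay content, rescaled from the reference 23 cm
    layer to the simulated depth.
    """
    clay = np.asarray(clay, dtype=float)
    if np.any(clay < 0.0) or np.any(clay > 100.0):
        raise ValueError("clay content must lie in [0, 100] %")
    return (20.0 + 1.3 * clay - 0.01 * clay**2) * depth / _TSMD_REF_DEPTH


def moisture_modifier_series(
    water_input,
    open_pan,
    clay,
    depth: float = 30.0,
    cover=None,
    deficit0=0.0,
    params: RothCParams = DEFAULT_PARAMS,
):
    """Moisture rate modifier ``b`` for 12 months, carrying the deficit.

    The accumulated deficit grows by ``0.75*open_pan - water`` in months
    where evaporation exceeds water input, and drains toward zero by the
    surplus otherwise.  Under bare soil the deficit cannot accrue beyond
    max/1.8.  The modifier is 1 while the deficit is below 0.444 of the
    maximum and declines linearly to ``min_moisture_modifier`` at the
    maximum.

    Parameters
    ----------
    water_input, open_pan : array_like, shape (..., 12)
        Precipitation plus irrigation, and open-pan evaporation, mm.
    cover : array_like of {0, 1}, shape (..., 12), optional
        Soil-cover flags; default fully covered.
    deficit0 : array_like
        Deficit carried in from the previous December (mm, >= 0).

    Returns
    -------
    (b, deficit) : modifiers shaped like the inputs, and the deficit to
        carry into the next year.
    """
    w = np.asarray(water_input, dtype=float)
    p = np.asarray(open_pan, dtype=float)
    if w.shape[-1] != 12 or p.shape[-1] != 12:
        raise ValueError("monthly series must have 12 entries on the last axis")
    if cover is None:
        cover = np.ones(12)
    cov = np.asarray(cover, dtype=float)
    maxd = max_topsoil_moisture_deficit(clay, depth)
    bare_cap = maxd / _BARE_DIVISOR

    batch = np.broadcast_shapes(w.shape[:-1], p.shape[:-1], np.shape(maxd), cov.shape[:-1])
    deficit = np.broadcast_to(np.asarray(deficit0, dtype=float), batch).copy()
    b = np.empty(batch + (12,), dtype=float)
    knee = _TSMD_KNEE * maxd
    bmin = params.min_moisture_modifier
    for m in range(12):
        et = 0.75 * p[..., m]
        accrual = et - w[..., m]
        covered = np.broadcast_to(cov[..., m] > 0, batch)
        cap = np.where(covered, maxd, np.maximum(bare_cap, deficit))
        deficit = np.where(
            accrual > 0.0,
            np.minimum(deficit + accrual, cap),
            np.maximum(deficit + accrual, 0.0),
        )
        b[..., m] = np.where(
            deficit <= knee,
            1.0,
            bmin + (1.0 - bmin) * (maxd - deficit) / (maxd - knee),
        )
    return b, deficit


def co2_partition(clay):
    """Fractions of decomposed carbon going to (CO2, BIO, HUM).

    The CO2/(BIO+HUM) ratio is ``x = 1.67*(1.85 + 1.60*exp(-0.0786*clay))``;
    CO2 takes ``x/(x+1)`` of the decomposed carbon and the remainder is
    split 46 % to BIO and 54 % to HUM.
    """
    clay = np.asarray(clay, dtype=float)
    x = 1.67 * (1.85 + 1.60 * np.exp(-0.0786 * clay))
    co2 = x / (x + 1.0)
    rest = 1.0 / (x + 1.0)
    return co2, 0.46 * rest, 0.54 * rest


def initialize_pools(soil: SoilProfile) -> PoolState:
    """Split an initial SOC stock into the five pools by pedotransfer.

    IOM follows the Falloon function ``0.049 * SOC**1.139``; RPM, HUM and
    BIO come from clay-dependent pedotransfer regressions; DPM is the
    non-negative residual.  If the regressions overshoot the stock, the
    residual is clipped at zero and the active pools are rescaled so the
    pool sum still equals the input stock (a warning is emitted).
    """
    soc = np.asarray(soil.soc0, dtype=float)
    clay = np.asarray(soil.clay, dtype=float)
    iom = 0.049 * soc**1.139
    rpm = (0.1847 * soc + 0.1555) * (clay + 1.2750) ** (-0.1158)
    hum = (0.7148 * soc + 0.5069) * (clay + 0.3421) ** 0.0184
    bio = (0.0140 * soc + 0.0075) * (clay + 8.8473) ** 0.0567
    dpm = soc - iom - rpm - hum - bio
    neg = dpm < 0.0
    if np.any(neg):
        warnings.warn(
            "pedotransfer pools exceed the initial stock; clipping DPM at 0 "
            "and rescaling RPM/HUM/BIO to conserve total SOC",
            RuntimeWarning,
            stacklevel=2,
        )
        active = rpm + hum + bio
        scale = np.where(neg, (soc - iom) / active, 1.0)
        rpm = rpm * scale
        hum = hum * scale
        bio = bio * scale
        dpm = np.where(neg, 0.0, dpm)
    return PoolState(dpm=dpm, rpm=rpm, bio=bio, hum=hum, iom=iom)


def step_month(
    state: PoolState,
    plant_c,
    fym_c,
    a,
    b,
    c,
    dpm_rpm_ratio,
    clay,
    params: RothCParams = DEFAULT_PARAMS,
):
    """Advance the pools by one month.

    Each active pool loses the fraction ``1 - exp(-k * a*b*c / 12)``; the
    decomposed carbon is partitioned into CO2, BIO and HUM by clay
    content.  Fresh plant carbon enters DPM and RPM in the land-use
    DPM/RPM ratio; farmyard manure enters by the fixed (0.49, 0.49, 0.02)
    split.  IOM is untouched.  Mass balance is exact: the change in total
    SOC equals inputs minus respired CO2.

    Returns
    -------
    (new_state, co2) : the updated pools and the respired carbon (t C/ha).
    """
    abc = np.asarray(a, float) * np.asarray(b, float) * np.asarray(c, float)
    if np.any(abc < 0.0):
        raise ValueError("rate modifiers must be non-negative")
    plant_c = np.asarray(plant_c, float)
    fym_c = np.asarray(fym_c, float)
    if np.any(plant_c < 0.0) or np.any(fym_c < 0.0):
        raise ValueError("carbon inputs must be non-negative")

    frac = lambda k: np.exp(-k * abc / 12.0)  # surviving fraction
    dpm_left = state.dpm * frac(params.k_dpm)
    rpm_left = state.rpm * frac(params.k_rpm)
    bio_left = state.bio * frac(params.k_bio)
    hum_left = state.hum * frac(params.k_hum)
    decomposed = (
        (state.dpm - dpm_left)
        + (state.rpm - rpm_left)
        + (state.bio - bio_left)
        + (state.hum - hum_left)
    )
    f_co2, f_bio, f_hum = co2_partition(clay)
    co2 = decomposed * f_co2

    ratio = np.asarray(dpm_rpm_ratio, float)
    if np.any(ratio <= 0.0):
        raise ValueError("dpm_rpm_ratio must be positive")
    to_dpm, to_rpm, to_hum_fym = params.fym_split
    new = PoolState(
        dpm=dpm_left + plant_c * ratio / (1.0 + ratio) + fym_c * to_dpm,
        rpm=rpm_left + plant_c / (1.0 + ratio) + fym_c * to_rpm,
        bio=bio_left + decomposed * f_bio,
        hum=hum_left + decomposed * f_hum + fym_c * to_hum_fym,
        iom=state.iom,
    )
    return new, co2


def run_years(
    state: PoolState,
    temp_modifier,
    cover,
    water_input,
    open_pan,
    plant_c,
    fym_c,
    dpm_rpm_ratio,
    clay,
    depth: float = 30.0,
    years: int = 1,
    params: RothCParams = DEFAULT_PARAMS,
    plant_year_scale=None,
    deficit0=0.0,
):
    """Run the kernel for a number of years under annually repeating forcing.

    Parameters
    ----------
    temp_modifier : array_like (..., 12)
        Precomputed monthly temperature modifiers.
    cover : array_like of {0, 1}, (12,) or (..., 12)
        Monthly soil-cover flags; covered months use the reduced cover
        rate modifier.
    water_input, open_pan : array_like (..., 12)
        Water forcing in mm (precipitation + irrigation; open-pan
        evaporation).  The topsoil moisture deficit persists across years.
    plant_c, fym_c : array_like (..., 12)
        Monthly carbon inputs, t C/ha.
    plant_year_scale : sequence of length ``years``, optional
        Multiplier applied to the plant input in each year (forest litter
        ramp); default constant 1.

    Returns
    -------
    (series, state) : SOC totals of shape ``(years+1, ...)`` with the
        initial total at index 0 and each December-end total after, and
        the final pool state.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    a = np.asarray(temp_modifier, dtype=float)
    cov = np.asarray(cover, dtype=float)
    w = np.asarray(water_input, dtype=float)
    p = np.asarray(open_pan, dtype=float)
    plant = np.asarray(plant_c, dtype=float)
    fym = np.asarray(fym_c, dtype=float)
    for name, arr in (("temp_modifier", a), ("cover", cov), ("water_input", w),
                      ("open_pan", p), ("plant_c", plant), ("fym_c", fym)):
        if arr.shape[-1] != 12:
            raise ValueError(f"{name} must have 12 monthly entries")
    if plant_year_scale is not None and len(plant_year_scale) != years:
        raise ValueError("plant_year_scale must have one entry per year")

    cmod = np.where(cov > 0, params.cover_modifier, 1.0)
    deficit = deficit0
    totals = [state.total()]
    for y in range(years):
        b, deficit = moisture_modifier_series(
            w, p, clay, depth, cov, deficit0=deficit, params=params
        )
        scale = 1.0 if plant_year_scale is None else plant_year_scale[y]
        for m in range(12):
            state, _ = step_month(
                state,
                plant[..., m] * scale,
                fym[..., m],
                a[..., m],
                b[..., m],
                cmod[..., m],
                dpm_rpm_ratio,
                clay,
                params,
            )
        totals.append(state.total())
    series = np.stack(np.broadcast_arrays(*(np.asarray(t, float) for t in totals)))
    return series, state
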