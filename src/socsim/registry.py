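"""Land-use class registry: default crop/forest/grassland parameters and
the enumeration of class x management combinations.

The default registry enumerates the 28 most produced and traded crops,
16 forest classes (two forest types in eight climatic zones) and one
grassland class.  Cereals appear under four management variants
(irrigated/rainfed x residues left/removed), other crops under
irrigated/rainfed only, and three vegetable crops are irrigated-only
(their rainfed area is negligible), which yields 80 classes in total.
Manure scenarios are a separate management axis and do not multiply the
class count.

Crop parameters (yield statistics, residue coefficients, calendars) are
registry configuration.  The bundled values are round, crop-plausible
defaults in the style of IPCC residue accounting, not a reproduction of
any national dataset; they can be overridden wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .carbon_inputs import LandUseSpec, ManagementSpec

__all__ = [
    "CROPS",
    "CEREALS",
    "IRRIGATED_ONLY",
    "PERMANENTS",
    "FOREST_TYPES",
    "IPCC_FOREST_ZONES",
    "FOREST_ZONE_TO_THERMAL",
    "GRASSLAND_ID",
    "LandUseClass",
    "default_kc_profile",
    "enumerate_lu_classes",
    "default_registry",
]

CEREALS = ("barley", "maize", "rice", "sorghum", "wheat")
IRRIGATED_ONLY = ("cabbages", "carrots", "onions")
PERMANENTS = (
    "apples", "bananas", "cocoa", "coconuts", "coffee",
    "grapes", "oil_palm", "olives", "oranges",
)

# name: (yield_mean t DM/ha, yield_sd, ag_slope, ag_intercept, bg_ratio,
#        sowing, harvest, pruning)
_CROP_TABLE = {
    "apples":         (6.0, 1.2, 0.3, 0.8, 0.25, None, None, 2),
    "bananas":        (8.0, 1.6, 0.5, 1.0, 0.20, None, None, 3),
    "barley":         (2.8, 0.6, 1.2, 0.6, 0.22, 3, 8, None),
    "cabbages":       (5.0, 1.0, 0.4, 0.3, 0.15, 3, 7, None),
    "carrots":        (4.5, 0.9, 0.4, 0.3, 0.15, 3, 8, None),
    "cocoa":          (1.2, 0.3, 0.8, 1.0, 0.30, None, None, 2),
    "coconuts":       (2.5, 0.5, 0.6, 1.0, 0.30, None, None, 2),
    "coffee":         (1.0, 0.25, 0.8, 1.0, 0.30, None, None, 2),
    "grapes":         (4.0, 0.8, 0.4, 0.8, 0.25, None, None, 1),
    "groundnuts":     (1.6, 0.35, 1.0, 0.5, 0.20, 5, 10, None),
    "maize":          (5.5, 1.1, 1.0, 0.6, 0.22, 4, 9, None),
    "oil_palm":       (4.0, 0.8, 0.8, 1.2, 0.25, None, None, 6),
    "olives":         (1.5, 0.35, 0.6, 0.8, 0.30, None, None, 2),
    "onions":         (4.0, 0.8, 0.3, 0.3, 0.15, 3, 8, None),
    "oranges":        (7.0, 1.4, 0.3, 0.8, 0.25, None, None, 3),
    "potatoes":       (7.5, 1.5, 0.3, 0.4, 0.20, 4, 9, None),
    "rapeseed":       (2.2, 0.45, 1.4, 0.4, 0.22, 9, 7, None),
    "rice":           (4.5, 0.9, 1.4, 0.0, 0.16, 5, 10, None),
    "seed_cotton":    (2.0, 0.4, 1.3, 0.4, 0.20, 4, 10, None),
    "sorghum":        (1.5, 0.4, 1.4, 0.0, 0.22, 5, 10, None),
    "soybeans":       (2.5, 0.5, 0.9, 0.7, 0.19, 5, 10, None),
    "sugar_beet":     (10.0, 2.0, 2.0, 0.0, 0.20, 4, 10, None),
    "sugar_cane":     (10.0, 2.0, 2.0, 0.0, 0.18, 3, 11, None),
    "sunflower":      (2.0, 0.4, 1.5, 0.4, 0.22, 4, 9, None),
    "sweet_potatoes": (6.0, 1.2, 0.3, 0.4, 0.20, 4, 9, None),
    "tobacco":        (1.5, 0.3, 1.8, 0.2, 0.20, 4, 9, None),
    "tomatoes":       (6.0, 1.2, 2.0, 0.0, 0.15, 4, 9, None),
    "wheat":          (3.0, 0.6, 1.3, 0.5, 0.23, 10, 7, None),
}

CROPS = tuple(sorted(_CROP_TABLE))

FOREST_TYPES = ("broadleaf_deciduous", "needleleaf_evergreen")

#: Eight climatic forest zones (IPCC-style), mapped to the four synthetic
#: thermal zones used by the atlas generator.
IPCC_FOREST_ZONES = (
    "dry_boreal", "moist_boreal",
    "dry_cold_temperate", "moist_cold_temperate",
    "dry_warm_temperate", "moist_warm_temperate",
    "subtropical", "tropical",
)
FOREST_ZONE_TO_THERMAL = {
    "dry_boreal": "boreal",
    "moist_boreal": "boreal",
    "dry_cold_temperate": "temperate",
    "moist_cold_temperate": "temperate",
    "dry_warm_temperate": "temperate",
    "moist_warm_temperate": "temperate",
    "subtropical": "subtropical",
    "tropical": "tropical",
}

#: Mature annual litter carbon (t C/ha/yr) per forest zone, broadleaf.
_FOREST_LITTER = {
    "dry_boreal": 0.8,
    "moist_boreal": 1.2,
    "dry_cold_temperate": 1.6,
    "moist_cold_temperate": 2.2,
    "dry_warm_temperate": 2.0,
    "moist_warm_temperate": 2.8,
    "subtropical": 3.5,
    "tropical": 4.5,
}
#: Needleleaf litter relative to broadleaf in the same zone.
_NEEDLELEAF_FACTOR = 0.85
_FOREST_MATURITY_YEARS = 20

GRASSLAND_ID = "grassland"

#: DPM/RPM partition of incoming plant carbon by broad land use.
DPM_RPM_CROPLAND = 1.44
DPM_RPM_GRASSLAND = 1.44  # improved-grassland default; 0.67 for unimproved
DPM_RPM_FOREST = 0.25


def default_kc_profile(sowing: Optional[int], harvest: Optional[int],
                       permanent: bool = False) -> np.ndarray:
    """Monthly crop-coefficient profile.

    Permanent crops keep a constant canopy coefficient all year.  Annual
    crops follow a trapezoid over the growing season: development ramp
    from 0.35 up to a mid-season 1.15 reached halfway through, then a
    late-season decline to 0.70 in the harvest month.  kc is zero outside
    the season.
    """
    if permanent:
        return np.full(12, 0.7)
    if sowing is None or harvest is None:
        raise ValueError("annual crop kc profile needs sowing and harvest months")
    kc = np.zeros(12)
    months = []
    m = int(sowing) - 1
    while True:
        months.append(m)
        if m == int(harvest) - 1:
            break
        m = (m + 1) % 12
    n = len(months)
    for i, mm in enumerate(months):
        if n == 1:
            kc[mm] = 0.7
        elif i == n - 1:
            kc[mm] = 0.7
        else:
            pos = i / (n - 1)
            kc[mm] = 0.35 + (1.15 - 0.35) * min(1.0, pos / 0.5)
    return kc


@dataclass(frozen=True)
class LandUseClass:
    """A registry entry: the land-use spec plus its management identity."""

    spec: LandUseSpec
    mgmt: ManagementSpec

    @property
    def class_id(self) -> str:
        return self.spec.class_id


def _crop_spec(name: str, params, cereals, permanents) -> LandUseSpec:
    ymean, ysd, slope, intercept, bg, sow, harv, prune = params
    permanent = name in permanents
    return LandUseSpec(
        class_id=name,
        broad_type="cropland",
        crop=name,
        is_cereal=name in cereals,
        is_permanent=permanent,
        sowing_month=sow,
        harvest_month=harv,
        pruning_month=prune,
        dpm_rpm_ratio=DPM_RPM_CROPLAND,
        yield_mean=ymean,
        yield_sd=ysd,
        ag_slope=slope,
        ag_intercept=intercept,
        bg_ratio=bg,
        kc_profile=default_kc_profile(sow, harv, permanent=permanent),
    )


def enumerate_lu_classes(
    crops: Optional[Mapping[str, tuple]] = None,
    cereals: Sequence[str] = CEREALS,
    irrigated_only: Sequence[str] = IRRIGATED_ONLY,
    forest_zones: Sequence[str] = IPCC_FOREST_ZONES,
    forest_types: Sequence[str] = FOREST_TYPES,
    n_grassland: int = 1,
) -> dict:
    """Build the class registry from the enumeration rules.

    Cereals expand to irrigated/rainfed x residues left/removed;
    irrigated-only crops to a single irrigated variant; remaining crops
    to irrigated/rainfed.  Each (forest type, zone) pair and the
    grassland class contribute one entry.  With the default inputs the
    registry holds exactly 80 classes.
    """
    if crops is None:
        crops = _CROP_TABLE
    cereals = tuple(cereals)
    irrigated_only = tuple(irrigated_only)
    for name in (*cereals, *irrigated_only):
        if name not in crops:
            raise ValueError(f"subset crop {name!r} not among the crops")
    if set(cereals) & set(irrigated_only):
        raise ValueError("cereal and irrigated-only subsets must be disjoint")

    registry: dict[str, LandUseClass] = {}

    def add(spec: LandUseSpec, mgmt: ManagementSpec) -> None:
        if spec.class_id in registry:
            raise ValueError(f"duplicate class id {spec.class_id!r}")
        registry[spec.class_id] = LandUseClass(spec=spec, mgmt=mgmt)

    for name in sorted(crops):
        base = _crop_spec(name, crops[name], cereals, PERMANENTS)
        if name in cereals:
            for irr in (True, False):
                for left in (True, False):
                    cid = (f"{name}__{'irr' if irr else 'rf'}"
                           f"__{'left' if left else 'removed'}")
                    add(replace(base, class_id=cid),
                        ManagementSpec(irrigated=irr, residues_left=left))
        elif name in irrigated_only:
            add(replace(base, class_id=f"{name}__irr"),
                ManagementSpec(irrigated=True))
        else:
            for irr in (True, False):
                add(replace(base, class_id=f"{name}__{'irr' if irr else 'rf'}"),
                    ManagementSpec(irrigated=irr))

    for zone in forest_zones:
        for ftype in forest_types:
            litter = _FOREST_LITTER.get(zone, 2.0)
            if ftype == "needleleaf_evergreen":
                litter *= _NEEDLELEAF_FACTOR
            spec = LandUseSpec(
                class_id=f"forest__{ftype}__{zone}",
                broad_type="forest",
                dpm_rpm_ratio=DPM_RPM_FOREST,
                forest_litter_mature=litter,
                forest_maturity_years=_FOREST_MATURITY_YEARS,
                thermal_zone=FOREST_ZONE_TO_THERMAL.get(zone, "temperate"),
            )
            add(spec, ManagementSpec(irrigated=False))

    for g in range(n_grassland):
        spec = LandUseSpec(
            class_id=GRASSLAND_ID if n_grassland == 1 else f"{GRASSLAND_ID}_{g+1}",
            broad_type="grassland",
            dpm_rpm_ratio=DPM_RPM_GRASSLAND,
            yield_mean=3.0,
            yield_sd=0.6,
            ag_slope=0.5,
            ag_intercept=0.0,
            bg_ratio=0.8,
        )
        add(spec, ManagementSpec(irrigated=False))

    return registry


def default_registry() -> dict:
    """The 80-class registry with bundled default parameters."""
    return enumerate_lu_classes()
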