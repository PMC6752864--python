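"""Monte-Carlo simulation driver and saturating-exponential reduction.

Each territorial unit x land-use class is simulated ``n_iter`` times.
Every iteration draws one concrete realization of all uncertain inputs
(monthly temperature and precipitation, clay, initial SOC, yield,
fertilizer nitrogen, stocking) from independent normal distributions
truncated at physical bounds, builds the water and carbon forcing,
initializes the pools by pedotransfer and runs the turnover kernel for
86 years.  The annual SOC series of each iteration is then reduced to
two parameters by least-squares fitting of the single-pool balance

    dSOC/dt = K - alpha * SOC
    SOC(t)  = K/alpha * (1 - exp(-alpha t)) + SOC0 * exp(-alpha t)

whose asymptote K/alpha is the attainable SOC stock and alpha the mean
mineralization rate.  Ensemble statistics (mean, sd, normal-theory 95 %
confidence intervals) summarize the 100 fits.

Rainfed crop yields are scaled by the seasonal water-sufficiency ratio
(in-season water supply over crop water requirement, capped at 1), so
water-limited units produce less residue carbon unless irrigated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import carbon_inputs as ci
from . import forcing as fc
from .registry import LandUseClass
from .rothc import (
    DEFAULT_PARAMS,
    PoolState,
    RothCParams,
    SoilProfile,
    initialize_pools,
    run_years,
    temperature_modifier,
)
from .synthetic import UHTURecord

__all__ = [
    "FeasibilityError",
    "FitError",
    "TrajectoryEnsemble",
    "FitResult",
    "EnsembleSummary",
    "draw_inputs",
    "simulate_uhtu_class",
    "fit_exponential",
    "fit_ensemble",
    "summarize_ensemble",
    "time_to_fraction",
    "run_atlas",
]

#: Fertilizer nitrogen applied on cropland, t N/ha/yr (mean, sd).
FERTILIZER_N = (0.10, 0.02)
#: Grazing intensity on grassland, livestock units/ha (mean, sd).
GRAZING_STOCKING = (0.5, 0.15)
#: Dung carbon excreted per livestock unit, t C/yr.
EXCRETION_C = 0.3

_CI_Z = 1.959963984540054  # two-sided normal 95 %


class FeasibilityError(ValueError):
    """The requested class is not feasible in the territorial unit."""


class FitError(RuntimeError):
    """The exponential reduction failed for an entire ensemble."""


def _truncated_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    """Normal draw truncated to [lo, hi] by rejection; sd=0 returns the mean."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    out = rng.normal(mean, sd, size=size)
    out = np.atleast_1d(np.asarray(out, dtype=float))
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not np.any(bad):
            break
        redraw = rng.normal(np.broadcast_to(mean, out.shape)[bad],
                            np.broadcast_to(sd, out.shape)[bad])
        out[bad] = redraw
    np.clip(out, lo, hi, out=out)
    return out if size is not None else out.reshape(np.broadcast(mean, sd).shape)


def draw_inputs(uhtu: UHTURecord, lu: LandUseClass, mgmt: ci.ManagementSpec,
                rng) -> dict:
    """Draw one concrete realization of all uncertain inputs.

    Every variable is drawn once from its normal distribution, truncated
    at its physical bounds (precipitation and yields non-negative, clay
    within [0, 100], SOC strictly positive).  Zero standard deviations
    reproduce the means exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    clim = uhtu.climate
    spec = lu.spec
    draw = {
        "temps": _truncated_normal(rng, clim.temp_mean, clim.temp_sd),
        "precip": _truncated_normal(rng, clim.precip_mean, clim.precip_sd, lo=0.0),
        "clay": float(_truncated_normal(
            rng, np.asarray(uhtu.soil.clay, float), uhtu.clay_sd, lo=0.0, hi=100.0)),
        "soc0": float(_truncated_normal(
            rng, np.asarray(uhtu.soil.soc0, float), uhtu.soc0_sd, lo=1e-6)),
    }
    if spec.yield_mean is not None:
        draw["yield_dm"] = float(_truncated_normal(
            rng, spec.yield_mean, spec.yield_sd, lo=0.0))
    if spec.broad_type == "cropland":
        draw["fert_n"] = float(_truncated_normal(
            rng, FERTILIZER_N[0], FERTILIZER_N[1], lo=0.0))
    if spec.broad_type == "grassland":
        draw["fert_n"] = float(_truncated_normal(
            rng, FERTILIZER_N[0], FERTILIZER_N[1], lo=0.0))
        draw["stocking"] = float(_truncated_normal(
            rng, GRAZING_STOCKING[0], GRAZING_STOCKING[1], lo=0.0))
    return draw


@dataclass
class TrajectoryEnsemble:
    """Annual SOC trajectories of one unit x class x management."""

    uhtu_id: str
    class_id: str
    mgmt: ci.ManagementSpec
    trajectories: np.ndarray  # (n_iter, years+1)
    iom: np.ndarray  # (n_iter,)
    seeds: np.ndarray  # per-iteration seeds
    mean_annual_irrigation_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.trajectories.ndim != 2:
            raise ValueError("trajectories must be (n_iter, years+1)")


@dataclass
class FitResult:
    """One fitted exponential: input rate K, mineralization rate alpha."""

    K: float  # t C/ha/yr
    alpha: float  # 1/yr
    soc0_used: float
    rss: float
    converged: bool = True

    @property
    def attainable_soc(self) -> float:
        return self.K / self.alpha


@dataclass
class EnsembleSummary:
    """Ensemble statistics of the fitted parameters."""

    K: np.ndarray
    alpha: np.ndarray
    attainable: np.ndarray
    n_converged: int
    K_mean: float = field(init=False)
    K_sd: float = field(init=False)
    alpha_mean: float = field(init=False)
    alpha_sd: float = field(init=False)
    attainable_mean: float = field(init=False)
    attainable_sd: float = field(init=False)
    attainable_ci: tuple = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.attainable)
        if n < 2:
            raise FitError("need at least two converged fits to summarize")
        self.K_mean = float(np.mean(self.K))
        self.K_sd = float(np.std(self.K, ddof=1))
        self.alpha_mean = float(np.mean(self.alpha))
        self.alpha_sd = float(np.std(self.alpha, ddof=1))
        self.attainable_mean = float(np.mean(self.attainable))
        self.attainable_sd = float(np.std(self.attainable, ddof=1))
        half = _CI_Z * self.attainable_sd / np.sqrt(n)
        self.attainable_ci = (self.attainable_mean - half,
                              self.attainable_mean + half)


def _exp_model(t, K, alpha, soc0):
    return K / alpha * (1.0 - np.exp(-alpha * t)) + soc0 * np.exp(-alpha * t)


def fit_exponential(series, soc0: Optional[float] = None,
                    start_year: int = 0) -> FitResult:
    """Fit the two-parameter balance model to an annual SOC series.

    The series is re-indexed so t=0 at ``start_year`` (forest classes fit
    post-maturity only) and SOC0 is fixed to the series value there.
    Positivity of K and alpha is enforced through bounds; on failure the
    fit is retried from a grid of initial mineralization rates, and a
    still-failing series is returned flagged rather than as silent NaN.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    y = series[start_year:]
    if len(y) < 3:
        raise ValueError("need at least 3 annual values beyond start_year")
    s0 = float(y[0]) if soc0 is None else float(soc0)
    t = np.arange(len(y), dtype=float)

    scale = max(1.0, float(np.max(np.abs(y))))
    if np.ptp(y) < 1e-9 * scale:
        # Equilibrium from the start: the asymptote is the constant level
        # and alpha is unidentifiable; report a nominal rate.
        alpha = 0.05
        return FitResult(K=alpha * float(y[-1]), alpha=alpha, soc0_used=s0,
                         rss=float(np.sum((y - y[-1]) ** 2)), converged=True)

    f = lambda tt, K, alpha: _exp_model(tt, K, alpha, s0)
    for alpha0 in (0.02, 0.005, 0.05, 0.1, 0.3, 1.0):
        k0 = max(alpha0 * float(y[-1]), 1e-9)
        try:
            popt, _ = curve_fit(
                f, t, y, p0=(k0, alpha0),
                bounds=((1e-12, 1e-9), (np.inf, 50.0)),
                maxfev=2000,
            )
        except (RuntimeError, ValueError):
            continue
        K, alpha = float(popt[0]), float(popt[1])
        resid = y - f(t, K, alpha)
        if np.all(np.isfinite(popt)):
            return FitResult(K=K, alpha=alpha, soc0_used=s0,
                             rss=float(resid @ resid), converged=True)
    return FitResult(K=np.nan, alpha=np.nan, soc0_used=s0, rss=np.nan,
                     converged=False)


def fit_ensemble(ens: TrajectoryEnsemble, start_year: int = 0) -> list:
    """Fit every iteration's trajectory separately."""
    return [fit_exponential(traj, start_year=start_year)
            for traj in ens.trajectories]


def summarize_ensemble(fits: Sequence[FitResult]) -> EnsembleSummary:
    """Mean, sd and 95 % CI of K, alpha and attainable SOC over an ensemble."""
    if len(fits) < 2:
        raise FitError("need at least two fits")
    ok = [f for f in fits if f.converged]
    if len(ok) < 2:
        raise FitError("fewer than two converged fits in the ensemble")
    return EnsembleSummary(
        K=np.array([f.K for f in ok]),
        alpha=np.array([f.alpha for f in ok]),
        attainable=np.array([f.attainable_soc for f in ok]),
        n_converged=len(ok),
    )


#: Yield response factor to seasonal water deficit (FAO-33 style):
#: relative yield loss per unit relative evapotranspiration deficit.
YIELD_RESPONSE_KY = 1.25


def _water_limited_yield_factor(precip, irrigation, requirement,
                                ky: float = YIELD_RESPONSE_KY):
    """Relative yield under the season's water supply (FAO-33 response).

    Water usable in a month is capped at that month's crop requirement
    (excess rain does not compensate another month); the seasonal
    sufficiency ratio q is the summed usable water over the summed
    requirement, and relative yield is ``max(0, 1 - ky * (1 - q))``.
    Irrigated schedules meet the requirement every month by construction
    and return 1.
    """
    req = np.asarray(requirement, dtype=float)
    usable = np.minimum(np.asarray(precip, float)
                        + np.asarray(irrigation, float), req)
    total_req = np.sum(req, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(total_req > 0.0, np.sum(usable, axis=-1) / total_req, 1.0)
    return np.maximum(0.0, 1.0 - ky * (1.0 - q))


def simulate_uhtu_class(
    uhtu: UHTURecord,
    lu: LandUseClass,
    mgmt: Optional[ci.ManagementSpec] = None,
    n_iter: int = 100,
    years: int = 86,
    seed: int = 0,
    params: RothCParams = DEFAULT_PARAMS,
    check_feasibility: bool = True,
) -> TrajectoryEnsemble:
    """Run the Monte-Carlo ensemble for one unit and land-use class.

    ``mgmt`` overrides the class's management (normally only to select a
    manure scenario).  The master seed deterministically spawns one seed
    per iteration; each iteration draws its own realization of all
    uncertain inputs.
    """
    if mgmt is None:
        mgmt = lu.mgmt
    spec = lu.spec
    if check_feasibility and lu.class_id not in uhtu.feasible_classes:
        raise FeasibilityError(
            f"class {lu.class_id!r} not feasible in {uhtu.uhtu_id!r}")

    master = np.random.default_rng(seed)
    iter_seeds = master.integers(0, 2**31 - 1, size=n_iter)
    draws = [draw_inputs(uhtu, lu, mgmt, int(s)) for s in iter_seeds]

    temps = np.stack([d["temps"] for d in draws])  # (n, 12)
    precip = np.stack([d["precip"] for d in draws])
    clay = np.array([d["clay"] for d in draws])
    soc0 = np.array([d["soc0"] for d in draws])

    water = fc.make_water_schedule(
        temps, precip, uhtu.climate.day_length, uhtu.climate.days_in_month,
        kc=spec.kc_profile, irrigated=bool(mgmt.irrigated),
    )

    # Annual plant carbon input.
    plant_year_scale = None
    if spec.broad_type == "forest":
        annual_c = np.full(n_iter, float(spec.forest_litter_mature))
        ramp = ci.forest_litter_schedule(spec, years)
        plant_year_scale = ramp / spec.forest_litter_mature
    else:
        ydraw = np.array([d["yield_dm"] for d in draws])
        if spec.broad_type == "cropland":
            ydraw = ydraw * _water_limited_yield_factor(
                precip, water.irrigation, water.requirement)
        residues_left = True if mgmt.residues_left is None else bool(mgmt.residues_left)
        annual_c = ci.annual_crop_residue_c(ydraw, spec, residues_left)
    plant_monthly = ci.distribute_monthly(annual_c, spec)

    # Farmyard manure and grazing dung, uniform over the year.
    fym_annual = np.zeros(n_iter)
    if spec.broad_type in ("cropland", "grassland") and mgmt.manure_scenario > 0:
        fert = np.array([d["fert_n"] for d in draws])
        fym_annual = fym_annual + ci.manure_c(fert, mgmt.manure_scenario)
    if spec.broad_type == "grassland":
        stock = np.array([d["stocking"] for d in draws])
        fym_annual = fym_annual + ci.grazing_dung_c(stock, EXCRETION_C)
    fym_monthly = np.broadcast_to((fym_annual / 12.0)[:, None], (n_iter, 12))

    cover = ci.soil_cover_flags(spec, mgmt)
    a = temperature_modifier(temps)
    state = initialize_pools(SoilProfile(clay=clay, soc0=soc0,
                                         depth=uhtu.soil.depth))
    series, final = run_years(
        state, a, cover, water.water_input, water.open_pan,
        plant_monthly, fym_monthly, spec.dpm_rpm_ratio, clay,
        depth=uhtu.soil.depth, years=years, params=params,
        plant_year_scale=plant_year_scale,
    )
    return TrajectoryEnsemble(
        uhtu_id=uhtu.uhtu_id,
        class_id=lu.class_id,
        mgmt=mgmt,
        trajectories=series.T.copy(),
        iom=np.asarray(final.iom, float).copy(),
        seeds=iter_seeds,
        mean_annual_irrigation_mm=float(np.mean(np.sum(water.irrigation, axis=-1))),
    )


def time_to_fraction(series, attainable: float, fraction: float = 0.95) -> int:
    """Years until the series settles within (1-fraction) of the initial
    gap around the asymptote.

    Uses the last time the trajectory is outside the band, so paths that
    dip and recover (forest transitions) are not credited for passing
    through early.  Censored at the series length if never settled.
    """
    series = np.asarray(series, dtype=float)
    gap0 = abs(attainable - series[0])
    if gap0 < 1e-12:
        return 0
    target = (1.0 - fraction) * gap0
    outside = np.nonzero(np.abs(attainable - series) > target)[0]
    if not outside.size:
        return 0
    if outside[-1] == len(series) - 1:
        return len(series)
    return int(outside[-1] + 1)


def run_atlas(
    uhtus: Sequence[UHTURecord],
    registry: dict,
    n_iter: int = 100,
    years: int = 86,
    seed: int = 0,
    class_ids: Optional[Sequence[str]] = None,
    manure_scenarios: Sequence[float] = (0.0,),
    params: RothCParams = DEFAULT_PARAMS,
    collect_per_iter: bool = True,
):
    """Simulate and fit every feasible unit x class x manure combination.

    Returns ``(results, per_iter)``: a summary DataFrame with one row per
    combination (ensemble statistics of K, alpha and attainable SOC, the
    years-to-95 % of the ensemble-mean trajectory and mean irrigation),
    and a long DataFrame of the individual fitted parameters (or None).
    """
    wanted = set(class_ids) if class_ids is not None else None
    master = np.random.default_rng(seed)
    rows, per_iter_rows = [], []
    for rec in uhtus:
        for cid in sorted(rec.feasible_classes):
            if cid not in registry or (wanted is not None and cid not in wanted):
                continue
            lu = registry[cid]
            spec = lu.spec
            scenarios = manure_scenarios if spec.broad_type != "forest" else (0.0,)
            for frac in scenarios:
                mgmt = ci.ManagementSpec(
                    irrigated=lu.mgmt.irrigated,
                    residues_left=lu.mgmt.residues_left,
                    manure_scenario=float(frac),
                )
                run_seed = int(master.integers(0, 2**31 - 1))
                ens = simulate_uhtu_class(
                    rec, lu, mgmt, n_iter=n_iter, years=years,
                    seed=run_seed, params=params,
                )
                start = (spec.forest_maturity_years
                         if spec.broad_type == "forest" else 0)
                fits = fit_ensemble(ens, start_year=start)
                summary = summarize_ensemble(fits)
                mean_traj = ens.trajectories.mean(axis=0)
                t95 = time_to_fraction(mean_traj, summary.attainable_mean)
                rows.append({
                    "uhtu_id": rec.uhtu_id,
                    "thermal_zone": rec.thermal_zone,
                    "class_id": cid,
                    "crop": spec.crop,
                    "broad_type": spec.broad_type,
                    "irrigated": bool(mgmt.irrigated),
                    "residues_left": mgmt.residues_left,
                    "manure_scenario": float(frac),
                    "K_mean": summary.K_mean,
                    "K_sd": summary.K_sd,
                    "alpha_mean": summary.alpha_mean,
                    "alpha_sd": summary.alpha_sd,
                    "attainable_mean": summary.attainable_mean,
                    "attainable_sd": summary.attainable_sd,
                    "attainable_ci_lo": summary.attainable_ci[0],
                    "attainable_ci_hi": summary.attainable_ci[1],
                    "n_converged": summary.n_converged,
                    "years_to_95pct": t95,
                    "mean_annual_irrigation_mm": ens.mean_annual_irrigation_mm,
                    "seed": run_seed,
                })
                if collect_per_iter:
                    for i, f in enumerate(fits):
                        if not f.converged:
                            continue
                        per_iter_rows.append({
                            "uhtu_id": rec.uhtu_id,
                            "class_id": cid,
                            "manure_scenario": float(frac),
                            "iteration": i,
                            "K": f.K,
                            "alpha": f.alpha,
                            "attainable": f.attainable_soc,
                        })
    results = pd.DataFrame(rows)
    per_iter = pd.DataFrame(per_iter_rows) if collect_per_iter else None
    return results, per_iter
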