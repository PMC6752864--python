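"""Management-effect summaries, cropland-vs-grassland comparison and export.

Management effects are paired per-unit differences of ensemble-mean
attainable SOC between two variants of the same crop (irrigated vs
rainfed, residues left vs removed, full manure vs none), aggregated to a
mean +/- sd across territorial units.  Cropland-vs-grassland contrasts
are tested per unit with one-way ANOVA on the two 100-member ensembles
of fitted attainable stocks; p-values are reported raw (no multiple-
testing correction), matching the per-unit 5 % convention used in
large-scale SOC assessments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .registry import GRASSLAND_ID, default_registry, enumerate_lu_classes

__all__ = [
    "EffectSummary",
    "management_effect",
    "compare_cropland_grassland",
    "export_results",
    "enumerate_lu_classes",
    "default_registry",
]


@dataclass
class EffectSummary:
    """Paired effect of one management contrast (or class pair)."""

    label: str
    per_uhtu: pd.DataFrame  # columns: uhtu_id, effect[, p_value]
    mean: float = field(init=False)
    sd: float = field(init=False)
    n: int = field(init=False)
    share_significant: float = field(init=False)

    def __post_init__(self) -> None:
        eff = self.per_uhtu["effect"].to_numpy(float)
        self.n = len(eff)
        self.mean = float(np.mean(eff)) if self.n else float("nan")
        self.sd = float(np.std(eff, ddof=1)) if self.n > 1 else float("nan")
        if "p_value" in self.per_uhtu.columns and self.n:
            p = self.per_uhtu["p_value"].to_numpy(float)
            self.share_significant = float(np.mean(p < 0.05))
        else:
            self.share_significant = float("nan")


_DIMENSIONS = {
    # dimension: (on/off column, keys identifying the counterpart)
    "irrigation": ("irrigated", ["uhtu_id", "crop", "residues_left",
                                 "manure_scenario"]),
    "residues": ("residues_left", ["uhtu_id", "crop", "irrigated",
                                   "manure_scenario"]),
}


def management_effect(results: pd.DataFrame, dimension: str) -> list:
    """Per-class paired effect of one management dimension.

    ``dimension`` is one of ``irrigation``, ``residues`` or ``manure``.
    For each crop class present in both variants, the effect is the
    per-unit difference of mean attainable SOC (on minus off); pairs
    whose counterpart variant is missing are skipped.  Returns one
    :class:`EffectSummary` per crop (label = crop name).
    """
    df = results[results["broad_type"] == "cropland"].copy()
    df["residues_left"] = df["residues_left"].astype(object).where(
        df["residues_left"].notna(), "n/a")
    if dimension == "manure":
        top = df["manure_scenario"].max()
        if top <= 0.0:
            return []
        on = df[df["manure_scenario"] == top]
        off = df[df["manure_scenario"] == 0.0]
        keys = ["uhtu_id", "class_id"]
    elif dimension in _DIMENSIONS:
        col, keys = _DIMENSIONS[dimension]
        on = df[df[col] == True]   # noqa: E712 - pandas elementwise
        off = df[df[col] == False]  # noqa: E712
    else:
        raise ValueError(f"unknown management dimension {dimension!r}")

    merged = on.merge(off, on=keys, suffixes=("_on", "_off"))
    if merged.empty:
        return []
    merged["effect"] = merged["attainable_mean_on"] - merged["attainable_mean_off"]
    crop_col = "crop" if "crop" in merged.columns else "crop_on"
    out = []
    for crop, grp in merged.groupby(crop_col, sort=True):
        out.append(EffectSummary(
            label=str(crop),
            per_uhtu=grp[["uhtu_id", "effect"]].reset_index(drop=True),
        ))
    return out


def compare_cropland_grassland(
    per_iter: pd.DataFrame,
    class_id: str,
    grassland_id: str = GRASSLAND_ID,
    manure_scenario: float = 0.0,
) -> EffectSummary:
    """Contrast one cropland class against grassland, unit by unit.

    For every territorial unit where both ensembles exist with at least
    two fits each, the effect is the difference of ensemble-mean
    attainable SOC (cropland minus grassland) and the p-value comes from
    one-way ANOVA on the two sets of fitted attainable values.
    ``share_significant`` is the fraction of units with p < 0.05 among
    those where the cropland attains more than the grassland.
    """
    sel = per_iter[per_iter["manure_scenario"] == manure_scenario]
    crop = sel[sel["class_id"] == class_id]
    grass = sel[sel["class_id"] == grassland_id]
    grass_by_uhtu = {u: g["attainable"].to_numpy(float)
                     for u, g in grass.groupby("uhtu_id")}
    rows = []
    for uhtu, cgrp in crop.groupby("uhtu_id"):
        c = cgrp["attainable"].to_numpy(float)
        g = grass_by_uhtu.get(uhtu, np.empty(0))
        if len(c) < 2 or len(g) < 2:
            continue
        if np.ptp(c) < 1e-12 and np.ptp(g) < 1e-12 and abs(c.mean() - g.mean()) < 1e-12:
            p = 1.0
        else:
            p = float(stats.f_oneway(c, g).pvalue)
            if not np.isfinite(p):
                p = 1.0
        rows.append({"uhtu_id": uhtu, "effect": float(c.mean() - g.mean()),
                     "p_value": p})
    per_uhtu = pd.DataFrame(rows, columns=["uhtu_id", "effect", "p_value"])
    summary = EffectSummary(label=f"{class_id} vs {grassland_id}",
                            per_uhtu=per_uhtu)
    positive = per_uhtu[per_uhtu["effect"] > 0]
    summary.share_significant = (
        float(np.mean(positive["p_value"] < 0.05)) if len(positive) else float("nan")
    )
    return summary


_RESULT_COLUMNS = [
    "uhtu_id", "thermal_zone", "class_id", "crop", "broad_type",
    "irrigated", "residues_left", "manure_scenario",
    "K_mean", "K_sd", "alpha_mean", "alpha_sd",
    "attainable_mean", "attainable_sd", "attainable_ci_lo", "attainable_ci_hi",
    "n_converged", "years_to_95pct", "mean_annual_irrigation_mm", "seed",
]


def export_results(results: pd.DataFrame, path, seed: Optional[int] = None,
                   config: Optional[dict] = None,
                   per_iter: Optional[pd.DataFrame] = None) -> Path:
    """Write the results table (stable column order) plus a run manifest.

    ``path`` is a directory; it receives ``results.csv``, an optional
    ``per_iteration.csv`` and ``manifest.json`` recording the seed and
    configuration.  Empty results are an explicit error, no files are
    written.
    """
    if results is None or results.empty:
        raise ValueError("refusing to export an empty results table")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    cols = [c for c in _RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(out / "results.csv", index=False)
    if per_iter is not None and not per_iter.empty:
        per_iter.to_csv(out / "per_iteration.csv", index=False)
    manifest = {
        "seed": seed,
        "n_rows": int(len(results)),
        "config": config or {},
        "columns": cols,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
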