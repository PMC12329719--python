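"""Policy scenario projection 2021-2035 and per-measure contribution analysis.

The scenario grid crosses three measure families, 2 x 3 x 3 = 18 combinations:

* management — NM (no management) vs IM (multistage wetland treatment);
* wetland restoration — WR1 (no expansion), WR2 (proportional placement,
  +180 km2/yr of natural wetland nationally), WR3 (the same net rate
  targeted at currently high-risk counties, re-targeted every year);
* antibiotic use abatement — 20%, 40% or 60% reduction at the source,
  phased in by farm participation: 0% of farms in 2020, +10 percentage
  points per year to 50% in 2025, then +5 per year to 100% in 2035.

Each projected year applies restoration, computes effective emissions,
routes them through the wetland inventory under the management mode, and
scores the high-risk county area (HRA).  Uncertainty bands rerun the whole
chain with individual bootstrap members.  The control-variable contribution
analysis averages, over scenario pairs identical in the other two factors
and over all years, the relative HRA reduction of each measure level against
its reference level (NM / WR1 / 20%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .regional import DEFAULT_HLR, NATURAL_CLASSES, assess_region, ensemble_are_fn
from .schema import FeatureSchema, default_schema
from .synthgen import AntibioticInventory, RegionState

__all__ = [
    "YEARS",
    "EXPANSION_RATE_KM2",
    "ScenarioSpec",
    "scenario_grid",
    "participation",
    "effective_emissions",
    "expand_wetlands",
    "HRASeries",
    "project",
    "contribution_analysis",
]

YEARS = tuple(range(2021, 2036))
EXPANSION_RATE_KM2 = 180.0

MANAGEMENTS = ("NM", "IM")
RESTORATIONS = ("WR1", "WR2", "WR3")
ABATEMENTS = (0.20, 0.40, 0.60)


@dataclass(frozen=True)
class ScenarioSpec:
    management: str
    restoration: str
    abatement: float

    def __post_init__(self) -> None:
        if self.management not in MANAGEMENTS:
            raise ValueError(f"unknown management {self.management!r}")
        if self.restoration not in RESTORATIONS:
            raise ValueError(f"unknown restoration {self.restoration!r}")
        if self.abatement not in ABATEMENTS:
            raise ValueError(f"unknown abatement rate {self.abatement!r}")

    @property
    def expansion_rate(self) -> float:
        return 0.0 if self.restoration == "WR1" else EXPANSION_RATE_KM2

    @property
    def id(self) -> str:
        return f"{self.management}-{self.restoration}-{round(self.abatement * 100)}"


def scenario_grid() -> list[ScenarioSpec]:
    """All 18 management x restoration x abatement combinations."""
    return [
        ScenarioSpec(m, w, a)
        for m in MANAGEMENTS
        for w in RESTORATIONS
        for a in ABATEMENTS
    ]


def participation(year: int) -> float:
    """Fraction of farms participating in antibiotic use reduction.

    0 in 2020, +0.10/yr through 2025 (0.50), then +0.05/yr through 2035
    (1.00), capped at 1.
    """
    if not 2020 <= year <= 2035:
        raise ValueError(f"year must be in [2020, 2035], got {year}")
    if year <= 2025:
        p = 0.10 * (year - 2020)
    else:
        p = 0.50 + 0.05 * (year - 2025)
    return min(p, 1.0)


def effective_emissions(e0, abatement: float, year: int):
    """Source emission after phased abatement: E0 x (1 - participation x rate)."""
    e0 = np.asarray(e0, dtype=float)
    if np.any(e0 < 0):
        raise ValueError("baseline emissions must be non-negative")
    if not 0.0 <= abatement <= 1.0:
        raise ValueError(f"abatement rate must be in [0, 1], got {abatement}")
    out = e0 * (1.0 - participation(year) * abatement)
    return float(out) if out.ndim == 0 else out


def _representative_features(
    pool: pd.DataFrame, fallback: pd.DataFrame, schema: FeatureSchema
) -> dict:
    """County-median numeric attributes and modal categoricals for new area."""
    src = pool if len(pool) else fallback
    out = {}
    for name in schema.numeric:
        out[name] = float(src[name].median())
    for name in schema.categorical:
        out[name] = src[name].mode().iloc[0]
    return out


def expand_wetlands(
    region: RegionState,
    restoration: str,
    year: int,
    high_risk_counties: list[str] | None = None,
    rate_km2: float = EXPANSION_RATE_KM2,
    schema: FeatureSchema | None = None,
) -> RegionState:
    """Apply one year of wetland restoration, returning a new region state.

    WR1 leaves the region unchanged.  WR2 adds ``rate_km2`` of natural-class
    wetland distributed across counties in proportion to their existing
    wetland area.  WR3 splits the same total equally among the counties
    currently classified high-risk (falling back to the WR2 distribution when
    none are).  New units carry county-median feature attributes.
    """
    if restoration not in RESTORATIONS:
        raise ValueError(f"unknown restoration {restoration!r}")
    if restoration == "WR1":
        return region.copy()
    schema = schema or default_schema()
    w = region.wetlands
    if restoration == "WR3" and high_risk_counties:
        targets = list(high_risk_counties)
        added = pd.Series(rate_km2 / len(targets), index=targets)
    else:
        by_county = w.groupby("county_id")["area_km2"].sum()
        if by_county.sum() == 0 or len(by_county) == 0:
            # degenerate region with no wetlands: split equally over counties
            ids = region.counties["county_id"]
            added = pd.Series(rate_km2 / len(ids), index=ids.to_numpy())
        else:
            added = rate_km2 * by_county / by_county.sum()
    rows = []
    for i, (cid, area) in enumerate(added.items()):
        if area <= 0:
            continue
        feats = _representative_features(w[w["county_id"] == cid], w, schema)
        rows.append(
            {
                "wetland_id": f"R{year}_{i:04d}",
                "county_id": cid,
                "wclass": "natural",
                "area_km2": float(area),
                **feats,
            }
        )
    new = RegionState(region.counties.copy(), region.wetlands.copy())
    if rows:
        new.wetlands = pd.concat(
            [new.wetlands, pd.DataFrame(rows)], ignore_index=True
        )
    return new


@dataclass
class HRASeries:
    """Yearly high-risk county area for one scenario, with a 95% band."""

    spec: ScenarioSpec
    table: pd.DataFrame  # year, hra_km2, band_low, band_high

    @property
    def hra(self) -> pd.Series:
        return self.table.set_index("year")["hra_km2"]


def _run_chain(
    spec: ScenarioSpec,
    region: RegionState,
    are_fn,
    inventory: AntibioticInventory,
    hlr: float,
    natural_classes,
) -> list[float]:
    state = region.copy()
    e0 = state.counties["emission_t"].to_numpy().copy()
    baseline = assess_region(state, inventory, are_fn, spec.management, hlr, natural_classes)
    high_risk = baseline.counties.loc[baseline.counties["high_risk"], "county_id"].tolist()
    out = []
    for year in YEARS:
        state = expand_wetlands(state, spec.restoration, year, high_risk)
        state.counties["emission_t"] = effective_emissions(e0, spec.abatement, year)
        ass = assess_region(state, inventory, are_fn, spec.management, hlr, natural_classes)
        high_risk = ass.counties.loc[ass.counties["high_risk"], "county_id"].tolist()
        out.append(ass.hra_km2)
    return out


def project(
    spec: ScenarioSpec,
    region: RegionState,
    ensemble,
    transform,
    inventory: AntibioticInventory,
    seed: int = 0,
    n_member_chains: int | None = 20,
    hlr: float = DEFAULT_HLR,
    schema: FeatureSchema | None = None,
    natural_classes=NATURAL_CLASSES,
) -> HRASeries:
    """Project the HRA trajectory 2021-2035 under one scenario.

    The point series uses the ensemble-mean predictor; the band reruns the
    full chain (expansion, abatement, allocation, risk) with each of
    ``n_member_chains`` bootstrap members (a seeded subsample when smaller
    than B) and takes 2.5/97.5 percentiles per year, widened if needed to
    bracket the point series.
    """
    schema = schema or default_schema()
    point = _run_chain(
        spec,
        region,
        ensemble_are_fn(ensemble, transform, schema),
        inventory,
        hlr,
        natural_classes,
    )
    members = getattr(ensemble, "members", [])
    if n_member_chains is None:
        chosen = list(members)
    elif n_member_chains >= len(members):
        chosen = list(members)
    else:
        idx = np.random.default_rng(seed).choice(
            len(members), size=n_member_chains, replace=False
        )
        chosen = [members[i] for i in idx]
    if chosen and len(chosen) > 1:
        runs = np.array(
            [
                _run_chain(
                    spec,
                    region,
                    ensemble_are_fn(m, transform, schema),
                    inventory,
                    hlr,
                    natural_classes,
                )
                for m in chosen
            ]
        )
        lo = np.minimum(np.percentile(runs, 2.5, axis=0), point)
        hi = np.maximum(np.percentile(runs, 97.5, axis=0), point)
    else:
        lo = hi = np.asarray(point)
    table = pd.DataFrame(
        {
            "year": list(YEARS),
            "hra_km2": point,
            "band_low": lo,
            "band_high": hi,
        }
    )
    return HRASeries(spec, table)


_REFERENCES = {"management": "NM", "restoration": "WR1", "abatement": 0.20}
_LEVELS = {
    "management": ["IM"],
    "restoration": ["WR2", "WR3"],
    "abatement": [0.40, 0.60],
}


def _level_id(level) -> str:
    return f"{round(level * 100)}" if isinstance(level, float) else str(level)


def contribution_analysis(
    series: Mapping[str, HRASeries | pd.DataFrame],
) -> pd.DataFrame:
    """Control-variable mean HRA reduction efficiency per measure level.

    For each non-reference level (IM; WR2, WR3; 40%, 60%) the efficiency is
    the mean over all scenario pairs identical in the other two factors and
    over all years of (HRA_ref - HRA_level) / HRA_ref; years with a zero
    reference HRA are skipped.  Returns one row per level plus the
    per-family mean across its levels.
    """
    grid = scenario_grid()
    missing = [s.id for s in grid if s.id not in series]
    if missing:
        raise ValueError(f"incomplete scenario grid, missing: {missing}")

    def hra_values(sid: str) -> np.ndarray:
        s = series[sid]
        t = s.table if isinstance(s, HRASeries) else s
        return np.asarray(t["hra_km2"], dtype=float)

    rows = []
    for family, levels in _LEVELS.items():
        fam_vals = []
        for level in levels:
            effs = []
            for spec in grid:
                if getattr(spec, family) != level:
                    continue
                ref_kwargs = {
                    "management": spec.management,
                    "restoration": spec.restoration,
                    "abatement": spec.abatement,
                }
                ref_kwargs[family] = _REFERENCES[family]
                ref = ScenarioSpec(**ref_kwargs)
                h_ref = hra_values(ref.id)
                h_lev = hra_values(spec.id)
                ok = h_ref > 0
                if ok.any():
                    effs.extend(((h_ref[ok] - h_lev[ok]) / h_ref[ok]).tolist())
            eff = float(np.mean(effs)) if effs else 0.0
            fam_vals.append(eff)
            rows.append(
                {"measure": family, "level": _level_id(level), "efficiency": eff}
            )
        rows.append(
            {
                "measure": family,
                "level": "(family mean)",
                "efficiency": float(np.mean(fam_vals)),
            }
        )
    return pd.DataFrame(rows)
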