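"""County-scale mass balance: allocation, removal, surplus, risk quotients.

Each county's annual antibiotic emission is routed through its wetland
inventory under one of two management modes:

* ``NM`` (no management) — the emission is distributed across all wetlands
  in proportion to wetland area, a single treatment pass;
* ``IM`` (improved, multistage management) — the entire emission is first
  treated by the constructed wetlands (engineered units, excluding
  reservoirs), area-proportionally; the summed first-stage surplus is then
  spread evenly across the remaining wetlands (natural wetlands and
  reservoirs) for a second pass — evenly per unit of wetland area by
  default (``stage2_share="area"``), or as equal mass shares per wetland
  (``stage2_share="mass"``).  Counties without constructed wetlands fall
  back to NM.

Per wetland, removal is AR = AI x ARE with the removal efficiency predicted
by the fitted model from the wetland's attributes and its influent
concentration; the county surplus is AS = emission - sum(AR), so mass is
conserved exactly.  Risk is scored by the cask-effect risk quotient

    RQ_total = c_surp / (n x PNEC_min),

where c_surp = c x (1 - ARE) is the surplus concentration, n the number of
antibiotic types emitted and PNEC_min the inventory's minimum predicted
no-effect concentration for algae: the aggregate risk is driven by the most
sensitive compound.  RQ > 1 flags high risk; the high-risk county area (HRA)
sums the land areas of counties containing at least one high-risk
natural-class wetland.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import FeatureSchema, default_schema
from .synthgen import CONSTRUCTED_CLASSES, AntibioticInventory, RegionState

__all__ = [
    "MODES",
    "NATURAL_CLASSES",
    "DEFAULT_HLR",
    "Allocation",
    "AllocationResult",
    "allocate",
    "concentration",
    "removal_and_surplus",
    "conc_surplus",
    "rq_total",
    "classify_risk",
    "hra",
    "assess_region",
    "RegionAssessment",
    "ensemble_are_fn",
]

MODES = ("NM", "IM")
#: wetland classes counted as "natural" when scoring the high-risk county
#: area (reservoirs are conserved water bodies, so they are included by
#: default; configurable)
NATURAL_CLASSES = ("natural", "reservoir")
#: hydraulic loading rate of the concentration model, m/d
DEFAULT_HLR = 0.5


def concentration(ai_t, area_km2, hlr_m_d: float = DEFAULT_HLR):
    """Influent concentration (ug/L) implied by an annual input mass.

    A dimensional throughput model: the annual water volume treated by a
    wetland is V = HLR x area x 1 yr, so c = AI / V.  This stand-in is
    deliberately isolated in one function so a site-specific concentration
    model can be dropped in.
    """
    ai_t = np.asarray(ai_t, dtype=float)
    area_km2 = np.asarray(area_km2, dtype=float)
    vol_m3 = hlr_m_d * area_km2 * 1e6 * 365.0
    return ai_t * 1e9 / vol_m3  # t -> ug, m3 -> L


#: how the first-stage surplus is shared among second-stage wetlands:
#: "area" spreads it evenly over the wetland surface (area-proportional
#: masses, hence one uniform second-stage concentration per county) and is
#: the default; "mass" gives every second-stage wetland an equal mass.
STAGE2_SHARES = ("area", "mass")
DEFAULT_STAGE2_SHARE = "area"


@dataclass
class Allocation:
    """Stage-wise input assignment for one county.

    ``stage1`` fixes input masses; ``stage2_ids`` lists the wetlands that
    will share the first-stage surplus (amounts resolved by
    :func:`removal_and_surplus` once stage-1 removal is known, split by
    ``stage2_share``).
    """

    county_id: str
    emission_t: float
    mode: str
    stage1: pd.DataFrame  # wetland_id, ai_t
    stage2_ids: list[str]
    stage2_share: str = DEFAULT_STAGE2_SHARE


def allocate(
    county: pd.Series,
    wetlands: pd.DataFrame,
    mode: str,
    stage2_share: str = DEFAULT_STAGE2_SHARE,
) -> Allocation:
    """Assign a county's emission to its wetlands under a management mode."""
    if stage2_share not in STAGE2_SHARES:
        raise ValueError(f"unknown stage2_share {stage2_share!r}")
    if mode not in MODES:
        raise ValueError(f"unknown management mode {mode!r}; choose from {MODES}")
    emission = float(county["emission_t"])
    if emission < 0:
        raise ValueError("emissions must be non-negative")
    cid = str(county["county_id"])
    if len(wetlands) == 0:
        warnings.warn(
            f"county {cid} has no wetlands: full emission becomes surplus",
            stacklevel=2,
        )
        return Allocation(cid, emission, mode, pd.DataFrame(columns=["wetland_id", "ai_t"]), [])

    constructed = wetlands[wetlands["wclass"].isin(CONSTRUCTED_CLASSES)]
    if mode == "IM" and len(constructed) > 0:
        share = constructed["area_km2"] / constructed["area_km2"].sum()
        stage1 = pd.DataFrame(
            {"wetland_id": constructed["wetland_id"].to_numpy(), "ai_t": emission * share.to_numpy()}
        )
        stage2 = wetlands.loc[
            ~wetlands["wetland_id"].isin(constructed["wetland_id"]), "wetland_id"
        ].tolist()
        return Allocation(cid, emission, "IM", stage1, stage2, stage2_share)

    share = wetlands["area_km2"] / wetlands["area_km2"].sum()
    stage1 = pd.DataFrame(
        {"wetland_id": wetlands["wetland_id"].to_numpy(), "ai_t": emission * share.to_numpy()}
    )
    return Allocation(cid, emission, mode, stage1, [])


@dataclass
class AllocationResult:
    """Resolved per-wetland mass balance for one county.

    ``wetlands`` columns: wetland_id, stage, ai_t, conc_ug_l, are (fraction),
    ar_t.  Invariant: emission == sum(ar_t) + surplus_t.
    """

    county_id: str
    emission_t: float
    mode: str
    wetlands: pd.DataFrame
    surplus_t: float

    @property
    def total_removal(self) -> float:
        return float(self.wetlands["ar_t"].sum())


def _stage_pass(
    assigned: pd.DataFrame, wetlands: pd.DataFrame, are_fn, hlr: float, stage: int
) -> pd.DataFrame:
    w = wetlands.set_index("wetland_id").loc[assigned["wetland_id"]]
    conc = concentration(assigned["ai_t"].to_numpy(), w["area_km2"].to_numpy(), hlr)
    feats = w.reset_index(drop=True).copy()
    feats["antibiotic_conc"] = conc
    are = np.clip(np.asarray(are_fn(feats), dtype=float), 0.0, 1.0)
    return pd.DataFrame(
        {
            "wetland_id": assigned["wetland_id"].to_numpy(),
            "stage": stage,
            "ai_t": assigned["ai_t"].to_numpy(),
            "conc_ug_l": conc,
            "are": are,
            "ar_t": assigned["ai_t"].to_numpy() * are,
        }
    )


def removal_and_surplus(
    alloc: Allocation,
    wetlands: pd.DataFrame,
    are_fn,
    hlr: float = DEFAULT_HLR,
) -> AllocationResult:
    """Resolve removal and surplus for one county's allocation.

    ``are_fn`` maps a feature table (the trial schema, with
    ``antibiotic_conc`` recomputed from the assigned input mass via the
    concentration model) to removal-efficiency fractions in [0, 1].
    """
    if len(alloc.stage1) == 0:
        return AllocationResult(
            alloc.county_id,
            alloc.emission_t,
            alloc.mode,
            pd.DataFrame(
                columns=["wetland_id", "stage", "ai_t", "conc_ug_l", "are", "ar_t"]
            ),
            alloc.emission_t,
        )
    parts = [_stage_pass(alloc.stage1, wetlands, are_fn, hlr, stage=1)]
    surplus = alloc.emission_t - float(parts[0]["ar_t"].sum())
    if alloc.stage2_ids:
        k = len(alloc.stage2_ids)
        if alloc.stage2_share == "mass":
            ai2 = np.full(k, surplus / k)
        else:
            areas = (
                wetlands.set_index("wetland_id")
                .loc[alloc.stage2_ids, "area_km2"]
                .to_numpy()
            )
            ai2 = surplus * areas / areas.sum()
        assigned2 = pd.DataFrame({"wetland_id": alloc.stage2_ids, "ai_t": ai2})
        parts.append(_stage_pass(assigned2, wetlands, are_fn, hlr, stage=2))
        surplus -= float(parts[1]["ar_t"].sum())
    return AllocationResult(
        alloc.county_id,
        alloc.emission_t,
        alloc.mode,
        pd.concat(parts, ignore_index=True),
        surplus,
    )


def conc_surplus(c: float, are: float) -> float:
    """Surplus concentration after treatment: c x (1 - ARE)."""
    if not 0.0 <= are <= 1.0:
        raise ValueError(f"removal efficiency must be a fraction in [0, 1], got {are}")
    if c < 0:
        raise ValueError("concentration must be non-negative")
    return c * (1.0 - are)


def rq_total(c_surp: float, n: int, pnec_min: float) -> float:
    """Cask-effect aggregate risk quotient: c_surp / (n x PNEC_min)."""
    if n < 1:
        raise ValueError(f"antibiotic-type count must be >= 1, got {n}")
    if pnec_min <= 0:
        raise ValueError(f"minimum PNEC must be positive, got {pnec_min}")
    if c_surp < 0:
        raise ValueError("surplus concentration must be non-negative")
    return c_surp / (n * pnec_min)


_BANDS = ((1.0, "high"), (0.1, "medium"), (0.01, "low"))


def classify_risk(rq: float) -> str:
    """Risk band: high (RQ > 1), medium (0.1, 1], low (0.01, 0.1], else no-risk."""
    if rq < 0:
        raise ValueError(f"risk quotient must be non-negative, got {rq}")
    for cut, band in _BANDS:
        if rq > cut:
            return band
    return "no-risk"


def _classify_vec(rq: np.ndarray) -> np.ndarray:
    return np.select([rq > 1.0, rq > 0.1, rq > 0.01], ["high", "medium", "low"], "no-risk")


def hra(
    counties: pd.DataFrame,
    wetlands: pd.DataFrame,
    natural_classes: tuple[str, ...] = NATURAL_CLASSES,
) -> float:
    """High-risk county area (km2): total land area of counties holding at
    least one high-risk natural-class wetland."""
    nat = wetlands[wetlands["wclass"].isin(natural_classes)]
    risky = set(nat.loc[nat["band"] == "high", "county_id"])
    return float(counties.loc[counties["county_id"].isin(risky), "area_km2"].sum())


@dataclass
class RegionAssessment:
    """Region-wide results: per-wetland mass balance + risk, county totals.

    Risk is scored at two granularities.  ``wetlands`` carries per-unit
    diagnostics; ``county_types`` aggregates each wetland class within a
    county (surplus mass over aggregate treated volume) and is what drives
    the county high-risk flag and the HRA, because the risk quotient is
    defined per wetland *type* at county scale.
    """

    mode: str
    wetlands: pd.DataFrame  # + stage, ai_t, conc_ug_l, are, ar_t, c_surp_ng_l, rq, band
    county_types: pd.DataFrame  # county_id, wclass, ai_t, ar_t, c_surp_ng_l, rq, band
    counties: pd.DataFrame  # + removal_t, surplus_t, high_risk
    hra_km2: float

    @property
    def total_removal(self) -> float:
        return float(self.counties["removal_t"].sum())

    @property
    def total_surplus(self) -> float:
        return float(self.counties["surplus_t"].sum())

    def summary(self) -> dict:
        bands = self.wetlands["band"].value_counts().to_dict()
        tbands = self.county_types["band"].value_counts().to_dict()
        return {
            "mode": self.mode,
            "total_emission_t": float(self.counties["emission_t"].sum()),
            "total_removal_t": self.total_removal,
            "total_surplus_t": self.total_surplus,
            "hra_km2": self.hra_km2,
            "band_counts": {k: int(v) for k, v in bands.items()},
            "type_band_counts": {k: int(v) for k, v in tbands.items()},
            "n_high_risk_counties": int(self.counties["high_risk"].sum()),
        }


def ensemble_are_fn(ensemble, transform, schema: FeatureSchema | None = None):
    """Adapter: bootstrap-ensemble mean prediction as an ARE fraction.

    Also accepts a single fitted member (anything with ``predict``), which is
    how member-wise uncertainty chains are run.
    """
    from .aremodel import BootstrapEnsemble, predict_are
    from .prep import apply_transform

    schema = schema or default_schema()

    def fn(feats: pd.DataFrame) -> np.ndarray:
        mat = apply_transform(feats[list(schema.names)], transform)
        if isinstance(ensemble, BootstrapEnsemble):
            pct = predict_are(ensemble, mat.to_numpy())["mean"].to_numpy()
        else:
            pct = np.clip(
                np.asarray(ensemble.predict(mat.to_numpy(dtype=float)), dtype=float),
                0.0,
                100.0,
            )
        return pct / 100.0

    return fn


def assess_region(
    region: RegionState,
    inventory: AntibioticInventory,
    are_fn,
    mode: str,
    hlr: float = DEFAULT_HLR,
    natural_classes: tuple[str, ...] = NATURAL_CLASSES,
    stage2_share: str = DEFAULT_STAGE2_SHARE,
) -> RegionAssessment:
    """Vectorized whole-region assessment (two predictor calls total).

    Equivalent to running :func:`allocate` + :func:`removal_and_surplus`
    county by county (asserted in the test suite), but batches all wetlands
    into a single stage-1 and a single stage-2 prediction so that scenario
    projections stay fast.
    """
    if mode not in MODES:
        raise ValueError(f"unknown management mode {mode!r}; choose from {MODES}")
    counties = region.counties.copy()
    w = region.wetlands.copy()
    if len(w) == 0:
        counties["removal_t"] = 0.0
        counties["surplus_t"] = counties["emission_t"]
        counties["high_risk"] = False
        empty = w.assign(
            stage=pd.Series(dtype=int),
            ai_t=pd.Series(dtype=float),
            rq=pd.Series(dtype=float),
            band=pd.Series(dtype=object),
        )
        ct = pd.DataFrame(
            columns=["county_id", "wclass", "ai_t", "ar_t", "c_surp_ng_l", "rq", "band"]
        )
        return RegionAssessment(mode, empty, ct, counties, 0.0)

    emis = counties.set_index("county_id")["emission_t"]
    is_constructed = w["wclass"].isin(CONSTRUCTED_CLASSES)
    cw_area = w.loc[is_constructed].groupby("county_id")["area_km2"].sum()
    all_area = w.groupby("county_id")["area_km2"].sum()

    if mode == "IM":
        has_cw = w["county_id"].map(cw_area).notna() & (
            w["county_id"].map(cw_area) > 0
        )
        multistage = has_cw  # counties with constructed wetlands
        stage1_mask = (is_constructed & multistage) | ~multistage
        denom = np.where(
            multistage, w["county_id"].map(cw_area), w["county_id"].map(all_area)
        )
    else:
        stage1_mask = pd.Series(True, index=w.index)
        multistage = pd.Series(False, index=w.index)
        denom = w["county_id"].map(all_area).to_numpy()

    ai1 = np.where(
        stage1_mask,
        w["county_id"].map(emis).to_numpy() * w["area_km2"].to_numpy() / denom,
        0.0,
    )
    conc1 = concentration(ai1, w["area_km2"].to_numpy(), hlr)
    feats = w.copy()
    feats["antibiotic_conc"] = np.where(stage1_mask, conc1, 0.0)
    are1 = np.clip(np.asarray(are_fn(feats), dtype=float), 0.0, 1.0)
    ar1 = ai1 * are1

    res = w[["wetland_id", "county_id", "wclass", "area_km2"]].copy()
    res["stage"] = np.where(stage1_mask, 1, 2)
    res["ai_t"] = ai1
    res["conc_ug_l"] = np.where(stage1_mask, conc1, 0.0)
    res["are"] = np.where(stage1_mask, are1, 0.0)
    res["ar_t"] = np.where(stage1_mask, ar1, 0.0)

    stage2_mask = ~np.asarray(stage1_mask, dtype=bool)
    if stage2_mask.any():
        removed1 = pd.Series(np.where(stage1_mask, ar1, 0.0), index=w.index).groupby(
            w["county_id"]
        ).sum()
        surplus1 = (emis - removed1.reindex(emis.index).fillna(0.0)).clip(lower=0.0)
        if stage2_share == "mass":
            k2 = pd.Series(stage2_mask, index=w.index).groupby(w["county_id"]).sum()
            share2 = 1.0 / np.maximum(w["county_id"].map(k2).to_numpy(), 1)
        elif stage2_share == "area":
            a2 = pd.Series(
                np.where(stage2_mask, w["area_km2"], 0.0), index=w.index
            )
            a2_tot = a2.groupby(w["county_id"]).sum()
            share2 = w["area_km2"].to_numpy() / np.maximum(
                w["county_id"].map(a2_tot).to_numpy(), 1e-300
            )
        else:
            raise ValueError(f"unknown stage2_share {stage2_share!r}")
        ai2 = np.where(
            stage2_mask,
            w["county_id"].map(surplus1).to_numpy() * share2,
            0.0,
        )
        conc2 = concentration(ai2, w["area_km2"].to_numpy(), hlr)
        feats2 = w.copy()
        feats2["antibiotic_conc"] = conc2
        are2 = np.clip(np.asarray(are_fn(feats2), dtype=float), 0.0, 1.0)
        res.loc[stage2_mask, "ai_t"] = ai2[stage2_mask]
        res.loc[stage2_mask, "conc_ug_l"] = conc2[stage2_mask]
        res.loc[stage2_mask, "are"] = are2[stage2_mask]
        res.loc[stage2_mask, "ar_t"] = (ai2 * are2)[stage2_mask]

    c_surp = res["conc_ug_l"].to_numpy() * (1.0 - res["are"].to_numpy()) * 1000.0
    res["c_surp_ng_l"] = c_surp
    rq = c_surp / (inventory.n * inventory.min_pnec)
    res["rq"] = rq
    res["band"] = _classify_vec(rq)

    # county x wetland-type aggregate: surplus mass over aggregate treated
    # volume (equivalently, the volume-weighted mean surplus concentration)
    res["_vol_m3"] = hlr * res["area_km2"].to_numpy() * 1e6 * 365.0
    res["_surp_mass_t"] = res["ai_t"] - res["ar_t"]
    grp = res.groupby(["county_id", "wclass"], as_index=False).agg(
        ai_t=("ai_t", "sum"),
        ar_t=("ar_t", "sum"),
        surp_t=("_surp_mass_t", "sum"),
        vol_m3=("_vol_m3", "sum"),
    )
    grp["c_surp_ng_l"] = grp["surp_t"] * 1e12 / grp["vol_m3"]  # t->ng, m3->L
    grp["rq"] = grp["c_surp_ng_l"] / (inventory.n * inventory.min_pnec)
    grp["band"] = _classify_vec(grp["rq"].to_numpy())
    county_types = grp.drop(columns=["surp_t", "vol_m3"])
    res = res.drop(columns=["_vol_m3", "_surp_mass_t"])

    removal_by_c = res.groupby("county_id")["ar_t"].sum()
    counties["removal_t"] = (
        counties["county_id"].map(removal_by_c).fillna(0.0).to_numpy()
    )
    counties["surplus_t"] = counties["emission_t"] - counties["removal_t"]
    nat = county_types[county_types["wclass"].isin(natural_classes)]
    risky = set(nat.loc[nat["band"] == "high", "county_id"])
    counties["high_risk"] = counties["county_id"].isin(risky)
    hra_km2 = float(counties.loc[counties["high_risk"], "area_km2"].sum())
    return RegionAssessment(mode, res, county_types, counties, hra_km2)
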