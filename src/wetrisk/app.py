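"""End-to-end pipeline orchestration.

:func:`run_pipeline` executes the full chain — synthetic data, imputation
and encoding, model tournament, bootstrap ensemble, regional assessment
under both management modes, the 18-scenario projection with contribution
analysis, and model interpretation — from a single :class:`RunConfig`, and
writes all artifacts (CSV tables plus a versioned, machine-readable
``summary.json``) into a run directory.  A run is reproducible from config
alone: one global seed fans out into fixed per-stage streams, and the
summary contains no timestamps, so identical configs produce byte-identical
summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aremodel, interpret, prep, regional, scenarios, synthgen
from .schema import TARGET, default_schema

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("wetrisk")

SUMMARY_SCHEMA_VERSION = 1
_REQUIRED_SUMMARY_KEYS = (
    "schema_version",
    "config",
    "model",
    "regional",
    "scenarios",
    "interpretation",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 1
    out_dir: str = "wetrisk_run"
    # synthetic data
    n_experiments: int = 337
    missing_rate: float = 0.1
    n_validation: int = 50
    n_counties: int = 60
    n_antibiotics: int = 80
    # modelling
    families: tuple[str, ...] = aremodel.FAMILIES
    searches: tuple[str, ...] = aremodel.SEARCH_METHODS
    train_frac: float = 0.8
    B: int = 100
    # regional / scenarios
    hlr_m_d: float = regional.DEFAULT_HLR
    natural_classes: tuple[str, ...] = regional.NATURAL_CLASSES
    n_member_chains: int = 12
    run_scenarios: bool = True
    # interpretation
    max_attr_rows: int = 60
    importance_repeats: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for f in ("families", "searches", "natural_classes"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage stream below 2**31."""
    return int(np.random.default_rng([seed, stage]).integers(2**31 - 1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_summary(path: Path, summary: dict) -> None:
    summary = _jsonable(summary)
    missing = [k for k in _REQUIRED_SUMMARY_KEYS if k not in summary]
    if missing:
        raise ValueError(f"summary schema violation, missing keys: {missing}")
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the populated output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = default_schema()
    seed = config.seed

    # --- synthetic data -----------------------------------------------------
    log.info("stage synthgen: n=%d counties=%d seed=%d",
             config.n_experiments, config.n_counties, seed)
    experiments = synthgen.gen_experiments(
        config.n_experiments, _stage_seed(seed, 1), config.missing_rate
    )
    validation = synthgen.gen_independent_validation(
        config.n_validation, _stage_seed(seed, 2)
    )
    region, inventory = synthgen.gen_region(
        config.n_counties, _stage_seed(seed, 3), config.n_antibiotics
    )
    synthgen.write_experiments(experiments, out / "experiments.csv",
                               seed=seed, missing_rate=config.missing_rate)
    synthgen.write_region(region, inventory, out / "region", seed=seed)

    # --- prep ---------------------------------------------------------------
    completed, imp_diffs = prep.impute_missforest(
        experiments, seed=_stage_seed(seed, 4)
    )
    train, test = prep.split(completed, _stage_seed(seed, 5), config.train_frac)
    transform = prep.fit_encode_scale(train, schema)
    X_train = prep.apply_transform(train, transform)
    X_test = prep.apply_transform(test, transform)
    y_train = train[TARGET].to_numpy()
    y_test = test[TARGET].to_numpy()
    log.info("stage prep: %d train / %d test rows, %d imputation sweeps",
             len(train), len(test), len(imp_diffs))

    # --- model tournament ---------------------------------------------------
    candidates = []
    for family in config.families:
        for search in config.searches:
            cand = aremodel.tune_and_train(
                X_train, y_train, family, search, seed=_stage_seed(seed, 6)
            ).evaluate(X_train, y_train, X_test, y_test)
            log.info("candidate %s/%s: cv_r2=%.3f test_r2=%.3f",
                     family, search, cand.cv_r2, cand.test_r2)
            candidates.append(cand)
    best, report = aremodel.select_best(candidates)
    report.to_csv(out / "model_report.csv", index=False)
    log.info("selected %s (%s): test R2=%.3f gap=%.3f",
             best.family, best.search_method, best.test_r2, best.overfit_gap)

    ensemble = aremodel.bootstrap_ensemble(
        X_train, y_train, best.family, best.params,
        B=config.B, seed=_stage_seed(seed, 7),
    )
    shuffle_drops = aremodel.validate_shuffle(
        best.model, X_test, y_test, seed=_stage_seed(seed, 8),
        column_groups=transform.column_groups(),
    )
    X_val = prep.apply_transform(validation, transform)
    _, ext = aremodel.validate_external(ensemble, X_val, validation[TARGET])

    # --- regional assessment (both modes) -----------------------------------
    are_fn = regional.ensemble_are_fn(ensemble, transform, schema)
    assessments = {}
    for mode in regional.MODES:
        ass = regional.assess_region(
            region, inventory, are_fn, mode,
            config.hlr_m_d, tuple(config.natural_classes),
        )
        ass.wetlands.to_csv(out / f"wetlands_{mode}.csv", index=False)
        ass.counties.to_csv(out / f"counties_{mode}.csv", index=False)
        assessments[mode] = ass
        log.info("regional %s: removal=%.1f t surplus=%.1f t hra=%.0f km2",
                 mode, ass.total_removal, ass.total_surplus, ass.hra_km2)
    nm, im = assessments["NM"], assessments["IM"]
    regional_summary = {
        "NM": nm.summary(),
        "IM": im.summary(),
        "im_removal_gain_pct": 100.0 * (im.total_removal - nm.total_removal)
        / nm.total_removal if nm.total_removal > 0 else 0.0,
        "im_surplus_drop_pct": 100.0 * (nm.total_surplus - im.total_surplus)
        / nm.total_surplus if nm.total_surplus > 0 else 0.0,
        "im_hra_drop_pct": 100.0 * (nm.hra_km2 - im.hra_km2) / nm.hra_km2
        if nm.hra_km2 > 0 else 0.0,
    }

    # --- scenarios -----------------------------------------------------------
    scen_summary: dict = {}
    if config.run_scenarios:
        series = {}
        for spec in scenarios.scenario_grid():
            s = scenarios.project(
                spec, region, ensemble, transform, inventory,
                seed=_stage_seed(seed, 9),
                n_member_chains=config.n_member_chains,
                hlr=config.hlr_m_d, schema=schema,
                natural_classes=tuple(config.natural_classes),
            )
            s.table.to_csv(out / f"scenario_{spec.id}.csv", index=False)
            series[spec.id] = s
        contrib = scenarios.contribution_analysis(series)
        contrib.to_csv(out / "contribution.csv", index=False)
        h0 = {sid: float(s.table["hra_km2"].iloc[0]) for sid, s in series.items()}
        hT = {sid: float(s.table["hra_km2"].iloc[-1]) for sid, s in series.items()}
        base_hra = nm.hra_km2
        scen_summary = {
            "n_scenarios": len(series),
            "hra_2021": h0,
            "hra_2035": hT,
            "hra_reduction_pct_vs_baseline": {
                sid: 100.0 * (base_hra - hT[sid]) / base_hra if base_hra > 0 else 0.0
                for sid in series
            },
            "contribution": contrib.to_dict(orient="records"),
        }
        log.info("scenarios: %d series projected", len(series))

    # --- interpretation -------------------------------------------------------
    Xa = X_test.iloc[: config.max_attr_rows]
    report_attr = interpret.attribute(
        best.model, Xa, transform.column_groups(), seed=_stage_seed(seed, 10)
    )
    report_attr.feature_phi.to_csv(out / "attributions.csv", index=False)
    shares = interpret.category_shares(report_attr, schema)
    imp = interpret.permutation_importance(
        best.model, X_test, y_test, repeats=config.importance_repeats,
        seed=_stage_seed(seed, 11), column_groups=transform.column_groups(),
    )
    imp.to_csv(out / "permutation_importance.csv", index=False)
    agreement = interpret.rank_agreement(report_attr, imp)
    log.info("interpretation: local-accuracy err=%.2e, rank agreement=%.2f",
             report_attr.local_accuracy_error(), agreement)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "config": config.to_dict(),
        "data": {
            "n_experiments": len(experiments),
            "n_train": len(train),
            "n_test": len(test),
            "imputation_sweeps": len(imp_diffs),
            "n_counties": len(region.counties),
            "n_wetlands": len(region.wetlands),
            "inventory_n": inventory.n,
            "inventory_min_pnec_ng_l": inventory.min_pnec,
        },
        "model": {
            "family": best.family,
            "search": best.search_method,
            "params": best.params,
            "cv_r2": best.cv_r2,
            "train_r2": best.train_r2,
            "test_r2": best.test_r2,
            "test_rmse": best.test_rmse,
            "overfit_gap": best.overfit_gap,
            "bootstrap_B": ensemble.B,
            "external_validation": ext,
            "shuffle_top5": shuffle_drops.head(5).to_dict(),
        },
        "regional": regional_summary,
        "scenarios": scen_summary,
        "interpretation": {
            "method": report_attr.method,
            "base_value": report_attr.base,
            "local_accuracy_error": report_attr.local_accuracy_error(),
            "category_shares_pct": shares.to_dict(),
            "rank_agreement_spearman": agreement,
            "top5_mean_abs": report_attr.mean_abs.head(5).to_dict(),
        },
    }
    _write_summary(out / "summary.json", summary)
    return out
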