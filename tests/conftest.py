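"""Shared fixtures: the canonical synthetic study and fitted models.

Expensive artifacts (the default 337-trial fixture, the five-family model
tournament, a bootstrap ensemble, a synthetic region) are session-scoped so
the whole suite pays for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

from wetrisk import aremodel, prep, synthgen
from wetrisk.schema import TARGET, default_schema

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

SEED = 1

warnings.filterwarnings("ignore", category=UserWarning, module="xgboost")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def study():
    """The canonical complete-data study: 337 trials, split, transform."""
    df = synthgen.gen_experiments(337, SEED, 0.0)
    train, test = prep.split(df, SEED)
    transform = prep.fit_encode_scale(train)
    return {
        "table": df,
        "train": train,
        "test": test,
        "transform": transform,
        "X_train": prep.apply_transform(train, transform),
        "X_test": prep.apply_transform(test, transform),
        "y_train": train[TARGET].to_numpy(),
        "y_test": test[TARGET].to_numpy(),
    }


@pytest.fixture(scope="session")
def tournament(study):
    """All five learner families tuned by grid search on the canonical study."""
    cands = [
        aremodel.tune_and_train(
            study["X_train"], study["y_train"], fam, "grid", seed=SEED
        ).evaluate(
            study["X_train"], study["y_train"], study["X_test"], study["y_test"]
        )
        for fam in aremodel.FAMILIES
    ]
    best, report = aremodel.select_best(cands)
    return {"candidates": cands, "best": best, "report": report}


@pytest.fixture(scope="session")
def ensemble(study, tournament):
    best = tournament["best"]
    return aremodel.bootstrap_ensemble(
        study["X_train"].to_numpy(),
        study["y_train"],
        best.family,
        best.params,
        B=30,
        seed=SEED,
    )


@pytest.fixture(scope="session")
def region_and_inventory():
    return synthgen.gen_region(60, SEED, 80)


@pytest.fixture(scope="session")
def toy_are_fn():
    """Gently decreasing ARE(conc): deterministic stand-in for the model."""

    def fn(feats):
        c = feats["antibiotic_conc"].to_numpy(dtype=float)
        return np.clip(0.9 - 0.08 * np.log10(np.maximum(c, 1e-12) + 1.0), 0.25, 0.95)

    return fn
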