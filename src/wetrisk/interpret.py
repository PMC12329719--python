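"""Model interpretation: additive attributions, category shares, importance.

Per-row, per-feature additive attributions (Shapley values) decompose each
prediction into a shared base value plus one contribution per feature, with
local accuracy: sum(attributions) + base == prediction.  Tree models
(XGBoost, scikit-learn trees/forests) get exact path-dependent attributions
from the in-house float64 TreeSHAP engine; any other regressor gets
permutation-sampling Shapley estimates against a background sample (seeded,
with a stated sample count), which also satisfy local accuracy exactly by
telescoping.

One-hot indicator columns are folded back onto their categorical feature by
summing their attributions, so reports are stated per original feature.
Category shares aggregate mean |attribution| over the four mechanistic
feature groups; a grouped permutation-importance ranking provides the
model-agnostic cross-check, with Spearman rank agreement between the two
orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from . import treeshap
from .aremodel import validate_shuffle
from .schema import GROUPS, FeatureSchema, default_schema

__all__ = [
    "AttributionReport",
    "attribute",
    "category_shares",
    "permutation_importance",
    "rank_agreement",
]


@dataclass
class AttributionReport:
    """Additive attributions for a set of rows.

    ``feature_phi`` holds one column per original feature (indicator columns
    already folded); ``prediction`` is the model output reconstructed by the
    attribution engine, so ``feature_phi.sum(axis=1) + base == prediction``
    to float64 round-off.
    """

    feature_phi: pd.DataFrame
    base: float
    prediction: np.ndarray
    method: str  # "treeshap" | "sampling"
    n_samples: int | None = None  # sampling method only

    @property
    def mean_abs(self) -> pd.Series:
        return self.feature_phi.abs().mean().sort_values(ascending=False)

    def local_accuracy_error(self) -> float:
        return float(
            np.abs(self.feature_phi.sum(axis=1).to_numpy() + self.base - self.prediction).max()
        )


def _fold_groups(
    phi: np.ndarray, columns: list[str], column_groups: dict[str, list[str]] | None
) -> pd.DataFrame:
    df = pd.DataFrame(phi, columns=columns)
    if not column_groups:
        return df
    out = {}
    for feat, cols in column_groups.items():
        out[feat] = df[[c for c in cols if c in df.columns]].sum(axis=1)
    return pd.DataFrame(out)


def _is_tree_model(model) -> bool:
    return isinstance(model, (XGBRegressor, RandomForestRegressor, DecisionTreeRegressor))


def attribute(
    model,
    X: pd.DataFrame,
    column_groups: dict[str, list[str]] | None = None,
    seed: int = 0,
    n_samples: int = 64,
    background_size: int = 32,
) -> AttributionReport:
    """Per-row additive attributions for a fitted regressor.

    Tree models use the exact TreeSHAP recursion; others use
    permutation-sampling Shapley with ``n_samples`` (permutation, background
    row) pairs shared across rows, permuting feature groups as whole units.
    """
    if not (hasattr(model, "predict")):
        raise ValueError("model must be a fitted regressor with .predict")
    Xv = X.to_numpy(dtype=float)
    cols = list(X.columns)
    if _is_tree_model(model):
        try:
            parsed = (
                treeshap.parse_xgboost(model)
                if isinstance(model, XGBRegressor)
                else treeshap.parse_sklearn(model, cols)
            )
        except Exception as exc:  # unfitted models have no booster/trees
            raise ValueError(f"model does not appear to be fitted: {exc}") from exc
        phi, base = treeshap.shap_values(parsed, Xv)
        pred = treeshap.predict(parsed, Xv)
        fp = _fold_groups(phi, cols, column_groups)
        return AttributionReport(fp, base, pred, "treeshap")

    # sampling Shapley over feature groups
    try:
        model.predict(Xv[:1])
    except Exception as exc:
        raise ValueError(f"model does not appear to be fitted: {exc}") from exc
    groups = column_groups or {c: [c] for c in cols}
    names = list(groups)
    gidx = [[cols.index(c) for c in groups[g]] for g in names]
    rng = np.random.default_rng(seed)
    bg = Xv[rng.choice(len(Xv), size=min(background_size, len(Xv)), replace=False)]
    n, d = len(Xv), len(names)
    phi = np.zeros((n, d))
    base = 0.0
    for _ in range(n_samples):
        perm = rng.permutation(d)
        b = bg[rng.integers(len(bg))]
        # insertion ladder per row: state 0 is the background, each step
        # copies one more feature group from x; telescoping over the ladder
        # gives sum_g phi_g == f(x) - f(b) exactly per sample
        ladder = np.empty((n, d + 1, Xv.shape[1]))
        cur = np.tile(b, (n, 1))
        ladder[:, 0, :] = cur
        for step, g in enumerate(perm, start=1):
            cur[:, gidx[g]] = Xv[:, gidx[g]]
            ladder[:, step, :] = cur
        preds = np.asarray(
            model.predict(ladder.reshape(n * (d + 1), -1)), dtype=float
        ).reshape(n, d + 1)
        base += float(preds[0, 0])  # f(b), row-independent
        for step, g in enumerate(perm, start=1):
            phi[:, g] += preds[:, step] - preds[:, step - 1]
    phi /= n_samples
    base /= n_samples
    pred = phi.sum(axis=1) + base
    fp = pd.DataFrame(phi, columns=names)
    return AttributionReport(fp, base, pred, "sampling", n_samples=n_samples)


def category_shares(
    report: AttributionReport, schema: FeatureSchema | None = None
) -> pd.Series:
    """Percent of total mean |attribution| per feature category (sums to 100)."""
    schema = schema or default_schema()
    ma = report.feature_phi.abs().mean()
    totals = dict.fromkeys(GROUPS, 0.0)
    for feat, val in ma.items():
        try:
            group = schema.group_of(str(feat))
        except KeyError:
            raise ValueError(f"feature {feat!r} is not mapped to a category") from None
        totals[group] += float(val)
    grand = sum(totals.values())
    if grand == 0.0:
        return pd.Series(totals, name="share_pct")
    return pd.Series(
        {g: 100.0 * v / grand for g, v in totals.items()}, name="share_pct"
    )


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    repeats: int = 5,
    seed: int = 0,
    column_groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Mean R^2 drop per feature under within-column permutation.

    Feature groups (one-hot blocks) are permuted jointly; the result is the
    model-agnostic ranking used to cross-check the attribution ranking.
    """
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    drops = validate_shuffle(
        model, X, y, seed=seed, repeats=repeats, column_groups=column_groups
    )
    out = drops.rename("importance").to_frame()
    out["rank"] = out["importance"].rank(ascending=False).astype(int)
    return out.reset_index(names="feature")


def rank_agreement(report: AttributionReport, importance: pd.DataFrame) -> float:
    """Spearman rank correlation between |attribution| and permutation ranks."""
    ma = report.feature_phi.abs().mean()
    imp = importance.set_index("feature")["importance"]
    common = [f for f in ma.index if f in imp.index]
    rho = spearmanr(ma[common].to_numpy(), imp[common].to_numpy()).statistic
    return float(rho)
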