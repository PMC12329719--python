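"""Assemble the modelling matrix: target, imputation, encoding, scaling, split.

The trial target is the mean antibiotic removal efficiency across the
antibiotic types measured in one experiment,

    ARE = (1 - sum_i c_eff_i / sum_i c_inf_i) * 100  [%],

i.e. one minus the mass-weighted remaining fraction.  Missing numeric cells
are completed by iterative random-forest imputation (the missForest scheme:
cycle through missing-bearing columns in order of increasing missingness,
regressing each on all the others, until the normalized change between
successive imputations first increases).  Categorical features are one-hot
encoded and numeric features z-scored with statistics fitted on the training
partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .schema import TARGET, FeatureSchema, default_schema

__all__ = [
    "mean_are",
    "impute_missforest",
    "FittedTransform",
    "fit_encode_scale",
    "apply_transform",
    "inverse_numeric",
    "split",
]


def mean_are(
    c_inf: Sequence[float],
    c_eff: Sequence[float],
    *,
    literal: bool = False,
) -> float:
    """Mean antibiotic removal efficiency (%) of one trial.

    Parameters
    ----------
    c_inf, c_eff
        Influent and effluent concentrations (ug/L), aligned per antibiotic
        type.  All influents must be positive; effluents non-negative.
    literal
        If True, return the remaining fraction ``sum(c_eff)/sum(c_inf)*100``
        instead of the removal efficiency (the two conventions differ by
        ``100 - x``).

    Negative efficiencies (effluent mass exceeding influent, which occurs in
    practice through desorption or transformation-product back-conversion)
    are returned as-is with a warning, not clipped.
    """
    inf = np.asarray(c_inf, dtype=float)
    eff = np.asarray(c_eff, dtype=float)
    if inf.shape != eff.shape or inf.ndim != 1 or inf.size == 0:
        raise ValueError("c_inf and c_eff must be equal-length 1-D sequences")
    if np.any(inf <= 0):
        raise ValueError("influent concentrations must all be positive")
    if np.any(eff < 0):
        raise ValueError("effluent concentrations must be non-negative")
    remaining = float(eff.sum() / inf.sum()) * 100.0
    if literal:
        return remaining
    are = 100.0 - remaining
    if are < 0:
        warnings.warn(
            f"negative removal efficiency ({are:.2f}%): effluent exceeds influent",
            stacklevel=2,
        )
    return are


def impute_missforest(
    table: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 10,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, list[float]]:
    """Iterative random-forest imputation of missing numeric cells.

    Missing cells are initialized with column means; columns with missing
    values are then visited in order of increasing missingness, each
    regressed on all other columns (categoricals enter the regressors as
    one-hot indicators; the target column, if present, is used too, as the
    reference algorithm uses every other variable).  Iteration stops when
    the normalized squared difference between successive imputations first
    increases, returning the previous iterate, or at ``max_iter``.

    Returns the completed table and the per-iteration difference statistic.
    Observed cells are never modified.
    """
    df = table.copy()
    num_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    na_counts = df[num_cols].isna().sum()
    for c in df.columns:
        if c not in num_cols and df[c].isna().any():
            raise ValueError(f"missing values in non-numeric column {c!r}")
        if df[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
    miss_cols = [c for c in num_cols if na_counts[c] > 0]
    if not miss_cols:
        return df, []
    if not any(df[c].notna().all() for c in df.columns):
        # at least one fully observed column is required to anchor the fit
        raise ValueError("no fully observed column available")

    masks = {c: df[c].isna().to_numpy() for c in miss_cols}
    for c in miss_cols:
        df.loc[masks[c], c] = df[c].mean()
    order = sorted(miss_cols, key=lambda c: int(na_counts[c]))

    def regressors(exclude: str) -> np.ndarray:
        parts = []
        for c in df.columns:
            if c == exclude:
                continue
            if pd.api.types.is_numeric_dtype(df[c]):
                parts.append(df[c].to_numpy(dtype=float)[:, None])
            else:
                parts.append(pd.get_dummies(df[c]).to_numpy(dtype=float))
        return np.hstack(parts)

    rng = np.random.default_rng(seed)
    prev = df[miss_cols].copy()
    diffs: list[float] = []
    best = df.copy()
    for _ in range(max_iter):
        for c in order:
            mask = masks[c]
            X = regressors(c)
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[~mask], df.loc[~mask, c].to_numpy(dtype=float))
            df.loc[mask, c] = rf.predict(X[mask])
        new = df[miss_cols]
        delta = float(
            ((new - prev) ** 2).to_numpy().sum() / (new**2).to_numpy().sum()
        )
        diffs.append(delta)
        if len(diffs) > 1 and delta > diffs[-2]:
            return best, diffs  # difference rose: keep the previous iterate
        best = df.copy()
        prev = new.copy()
    return best, diffs


@dataclass
class FittedTransform:
    """Training-set encoding/scaling statistics.

    Numeric columns are z-scored with the stored means/sds (population sd);
    categorical columns expand to one indicator per training-seen level.
    Zero-variance numerics map to all-zeros; unseen test levels map to
    all-zero indicators.  Both degenerate cases warn.
    """

    schema: FeatureSchema
    means: dict[str, float]
    sds: dict[str, float]
    vocab: dict[str, tuple[str, ...]]

    @property
    def columns(self) -> list[str]:
        cols = list(self.means)
        for feat, levels in self.vocab.items():
            cols += [f"{feat}={lvl}" for lvl in levels]
        return cols

    def column_groups(self) -> dict[str, list[str]]:
        """Encoded-column names grouped by original feature."""
        groups = {c: [c] for c in self.means}
        for feat, levels in self.vocab.items():
            groups[feat] = [f"{feat}={lvl}" for lvl in levels]
        return groups


def fit_encode_scale(
    table: pd.DataFrame, schema: FeatureSchema | None = None
) -> FittedTransform:
    """Fit z-score and one-hot statistics on a (training) table."""
    schema = schema or default_schema()
    schema.validate_table(table.columns)
    means, sds, vocab = {}, {}, {}
    for name in schema.numeric:
        col = table[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"numeric column {name!r} still has missing values")
        means[name] = float(col.mean())
        sd = float(col.std(ddof=0))
        if sd == 0.0:
            warnings.warn(
                f"zero-variance column {name!r}: mapped to all-zeros", stacklevel=2
            )
        sds[name] = sd
    for name in schema.categorical:
        vocab[name] = tuple(sorted(table[name].astype(str).unique()))
    return FittedTransform(schema, means, sds, vocab)


def apply_transform(table: pd.DataFrame, ft: FittedTransform) -> pd.DataFrame:
    """Encode and scale a table with previously fitted statistics."""
    out = {}
    for name, mu in ft.means.items():
        sd = ft.sds[name]
        col = table[name].to_numpy(dtype=float)
        out[name] = np.zeros_like(col) if sd == 0.0 else (col - mu) / sd
    for feat, levels in ft.vocab.items():
        vals = table[feat].astype(str).to_numpy()
        unseen = ~np.isin(vals, levels)
        if unseen.any():
            warnings.warn(
                f"{int(unseen.sum())} unseen level(s) in {feat!r} map to all-zero "
                "indicators",
                stacklevel=2,
            )
        for lvl in levels:
            out[f"{feat}={lvl}"] = (vals == lvl).astype(float)
    return pd.DataFrame(out, index=table.index)[ft.columns]


def inverse_numeric(mat: pd.DataFrame, ft: FittedTransform) -> pd.DataFrame:
    """Undo the z-scoring of the numeric block (round-trip check helper)."""
    out = {}
    for name, mu in ft.means.items():
        sd = ft.sds[name]
        out[name] = mat[name].to_numpy(dtype=float) * sd + mu
    return pd.DataFrame(out, index=mat.index)


def split(
    table: pd.DataFrame, seed: int, train_frac: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint train/test row partition.

    Train size is ``floor(n * train_frac + 0.5)`` (round half up).
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    n = len(table)
    if n < 5:
        raise ValueError(f"need at least 5 rows to split, got {n}")
    n_train = int(np.floor(n * train_frac + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    train = table.iloc[np.sort(perm[:n_train])]
    test = table.iloc[np.sort(perm[n_train:])]
    return train, test
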