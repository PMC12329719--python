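"""Exact path-dependent Shapley attributions for tree ensembles.

Implements the polynomial-time TreeSHAP recursion (Lundberg et al.'s
path-dependent algorithm) in float64 on a neutral parsed-tree
representation, with parsers for XGBoost boosters and scikit-learn
decision-tree/forest regressors.  The conditional expectation for a feature
outside the coalition follows the tree's training cover (node sample
weights), so the base value is the cover-weighted mean tree output and

    sum_j phi_j + base == f(x)

holds exactly (float64 round-off) for every row, where ``f`` is the float64
traversal of the same trees (:func:`predict`).  Attributions for features a
tree never splits on are exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ParsedTrees", "parse_xgboost", "parse_sklearn", "shap_values", "predict"]


@dataclass
class _Tree:
    children_left: np.ndarray  # -1 for leaf
    children_right: np.ndarray
    feature: np.ndarray  # -1 for leaf
    threshold: np.ndarray
    value: np.ndarray  # leaf value (already scaled for averaging ensembles)
    cover: np.ndarray  # training sample weight per node
    cmp: str  # "lt": go left if x < t (xgboost); "le": x <= t (sklearn)

    def goes_left(self, x: np.ndarray, node: int) -> bool:
        xv = x[self.feature[node]]
        t = self.threshold[node]
        if self.cmp == "lt":
            # xgboost stores thresholds and compares in float32; mirror that
            # so ties at training values resolve identically
            return bool(np.float32(xv) < np.float32(t))
        return bool(xv <= t)


@dataclass
class ParsedTrees:
    trees: list[_Tree]
    base: float  # additive offset (xgboost base_score; 0 for sklearn)
    n_features: int
    feature_names: list[str] | None = None

    @property
    def expected_value(self) -> float:
        """Cover-weighted mean output: the attribution base value."""
        total = self.base
        for t in self.trees:
            leaves = t.children_left < 0
            total += float(
                (t.value[leaves] * t.cover[leaves]).sum() / t.cover[0]
            )
        return total


def parse_xgboost(model) -> ParsedTrees:
    """Parse an ``xgboost.XGBRegressor`` (or Booster) into float64 trees."""
    booster = model.get_booster() if hasattr(model, "get_booster") else model
    cfg = json.loads(booster.save_config())
    base = float(cfg["learner"]["learner_model_param"]["base_score"])
    names = booster.feature_names
    dumps = booster.get_dump(dump_format="json", with_stats=True)
    trees = []
    for s in dumps:
        nodes: dict[int, dict] = {}

        def walk(nd: dict) -> None:
            nodes[nd["nodeid"]] = nd
            for ch in nd.get("children", ()):
                walk(ch)

        walk(json.loads(s))
        size = max(nodes) + 1
        cl = np.full(size, -1, dtype=np.int64)
        cr = np.full(size, -1, dtype=np.int64)
        feat = np.full(size, -1, dtype=np.int64)
        thr = np.zeros(size)
        val = np.zeros(size)
        cov = np.zeros(size)
        for i, nd in nodes.items():
            cov[i] = float(nd["cover"])
            if "leaf" in nd:
                val[i] = float(nd["leaf"])
            else:
                cl[i] = int(nd["yes"])
                cr[i] = int(nd["no"])
                f = nd["split"]
                feat[i] = names.index(f) if names else int(str(f).lstrip("f"))
                thr[i] = float(nd["split_condition"])
        trees.append(_Tree(cl, cr, feat, thr, val, cov, "lt"))
    n_features = int(booster.num_features())
    return ParsedTrees(trees, base, n_features, list(names) if names else None)


def parse_sklearn(model, feature_names: list[str] | None = None) -> ParsedTrees:
    """Parse a scikit-learn tree or forest regressor (leaf values scaled by
    1/n_estimators so the ensemble output is the tree sum)."""
    ests = list(getattr(model, "estimators_", [model]))
    scale = 1.0 / len(ests)
    trees = []
    for est in ests:
        t = est.tree_
        trees.append(
            _Tree(
                t.children_left.astype(np.int64),
                t.children_right.astype(np.int64),
                t.feature.astype(np.int64),
                t.threshold.astype(float),
                t.value[:, 0, 0].astype(float) * scale,
                t.weighted_n_node_samples.astype(float),
                "le",
            )
        )
    return ParsedTrees(trees, 0.0, int(model.n_features_in_), feature_names)


def predict(parsed: ParsedTrees, X: np.ndarray) -> np.ndarray:
    """Float64 traversal prediction of the parsed ensemble."""
    X = np.asarray(X, dtype=float)
    out = np.full(len(X), parsed.base)
    for t in parsed.trees:
        for r in range(len(X)):
            node = 0
            while t.children_left[node] >= 0:
                node = (
                    t.children_left[node]
                    if t.goes_left(X[r], node)
                    else t.children_right[node]
                )
            out[r] += t.value[node]
    return out


# --- the TreeSHAP path recursion -------------------------------------------
# Path state is four parallel lists (unique feature index, zero fraction,
# one fraction, permutation weight); every recursion level works on copies,
# as in the reference algorithm.


def _extend(fi, zf, of, pw, pz, po, pidx):
    depth = len(fi)
    fi.append(pidx)
    zf.append(pz)
    of.append(po)
    pw.append(1.0 if depth == 0 else 0.0)
    for i in range(depth - 1, -1, -1):
        pw[i + 1] += po * pw[i] * (i + 1) / (depth + 1)
        pw[i] = pz * pw[i] * (depth - i) / (depth + 1)


def _unwind(fi, zf, of, pw, path_index):
    depth = len(fi) - 1
    one = of[path_index]
    zero = zf[path_index]
    nxt = pw[depth]
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = pw[i]
            pw[i] = nxt * (depth + 1) / ((i + 1) * one)
            nxt = tmp - pw[i] * zero * (depth - i) / (depth + 1)
        else:
            pw[i] = pw[i] * (depth + 1) / (zero * (depth - i))
    for i in range(path_index, depth):
        fi[i], zf[i], of[i] = fi[i + 1], zf[i + 1], of[i + 1]
    fi.pop(), zf.pop(), of.pop(), pw.pop()


def _unwound_sum(zf, of, pw, path_index):
    depth = len(zf) - 1
    one = of[path_index]
    zero = zf[path_index]
    nxt = pw[depth]
    total = 0.0
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = nxt * (depth + 1) / ((i + 1) * one)
            total += tmp
            nxt = pw[i] - tmp * zero * (depth - i) / (depth + 1)
        else:
            total += pw[i] * (depth + 1) / (zero * (depth - i))
    return total


def _recurse(t: _Tree, x, phi, node, fi, zf, of, pw, pz, po, pidx):
    fi, zf, of, pw = list(fi), list(zf), list(of), list(pw)
    _extend(fi, zf, of, pw, pz, po, pidx)
    depth = len(fi) - 1
    if t.children_left[node] < 0:
        v = t.value[node]
        for i in range(1, depth + 1):
            w = _unwound_sum(zf, of, pw, i)
            phi[fi[i]] += w * (of[i] - zf[i]) * v
        return
    f = int(t.feature[node])
    if t.goes_left(x, node):
        hot, cold = t.children_left[node], t.children_right[node]
    else:
        hot, cold = t.children_right[node], t.children_left[node]
    iz = io = 1.0
    k = next((i for i in range(1, depth + 1) if fi[i] == f), 0)
    if k > 0:
        iz, io = zf[k], of[k]
        _unwind(fi, zf, of, pw, k)
    hot_zero = t.cover[hot] / t.cover[node] * iz
    cold_zero = t.cover[cold] / t.cover[node] * iz
    _recurse(t, x, phi, hot, fi, zf, of, pw, hot_zero, io, f)
    _recurse(t, x, phi, cold, fi, zf, of, pw, cold_zero, 0.0, f)


def shap_values(parsed: ParsedTrees, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-row, per-feature attributions and the shared base value.

    Returns ``(phi, base)`` with ``phi.shape == (n_rows, n_features)`` and
    ``phi.sum(axis=1) + base == predict(parsed, X)`` to float64 round-off.
    """
    X = np.asarray(X, dtype=float)
    phi = np.zeros((len(X), parsed.n_features))
    for t in parsed.trees:
        for r in range(len(X)):
            _recurse(t, X[r], phi[r], 0, [], [], [], [], 1.0, 1.0, -1)
    return phi, parsed.expected_value
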