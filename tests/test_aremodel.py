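"""Model tournament, selection rules, bootstrap ensemble, validations."""

import numpy as np
import pandas as pd
import pytest

from wetrisk import aremodel, prep, synthgen
from wetrisk.schema import TARGET


class _Const:
    """Stub regressor predicting a constant (for clip-rule checks)."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value, dtype=float)


class TestTuneAndTrain:
    def test_recovers_noiseless_linear_signal(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("abcd"))
        y = 3 * X["a"].to_numpy() - 2 * X["c"].to_numpy()
        cand = aremodel.tune_and_train(X, y, "random_forest", "grid", seed=1)
        assert cand.cv_r2 >= 0.9

    @pytest.mark.parametrize("fam,search", [("neuralnet", "grid"), ("xgboost", "annealing")])
    def test_unknown_family_or_search_rejected(self, fam, search):
        X = pd.DataFrame(np.zeros((30, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            aremodel.tune_and_train(X, np.zeros(30), fam, search)

    def test_too_few_rows_for_cv(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 2)))
        with pytest.raises(ValueError):
            aremodel.tune_and_train(X, np.zeros(20), "knn")

    def test_random_and_bayes_search_run(self, study):
        for search in ("random", "bayes"):
            cand = aremodel.tune_and_train(
                study["X_train"], study["y_train"], "knn", search, seed=2
            )
            assert np.isfinite(cand.cv_r2)
            assert cand.n_evals >= 5


class TestSelectBest:
    def _cand(self, family, test_r2, test_rmse, train_r2=0.9):
        c = aremodel.CandidateModel(family, "grid", {}, 0.5, 1.0, _Const(0), 1)
        c.train_r2, c.train_rmse = train_r2, 1.0
        c.test_r2, c.test_rmse = test_r2, test_rmse
        return c

    def test_highest_heldout_r2_wins(self):
        best, _ = aremodel.select_best(
            [self._cand("A", 0.80, 9.0), self._cand("B", 0.90, 9.0)]
        )
        assert best.family == "B"

    def test_rmse_breaks_ties(self):
        best, _ = aremodel.select_best(
            [self._cand("A", 0.85, 9.0), self._cand("B", 0.85, 6.5)]
        )
        assert best.family == "B"

    def test_overfit_gap_flagged(self):
        _, report = aremodel.select_best(
            [self._cand("A", 0.70, 9.0, train_r2=0.90)]
        )
        assert report.loc[0, "overfit_risk"] == True  # gap 0.20 >= 0.15

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aremodel.select_best([])


class TestBootstrapEnsemble:
    def test_single_member_zero_uncertainty(self, study):
        ens = aremodel.bootstrap_ensemble(
            study["X_train"].to_numpy(), study["y_train"], "knn",
            {"n_neighbors": 5}, B=1, seed=0,
        )
        out = aremodel.predict_are(ens, study["X_test"].to_numpy())
        assert (out["sd"] == 0).all()
        assert (out["ci_high"] - out["ci_low"] == 0).all()

    def test_constant_target_gives_constant_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        y = np.full(50, 42.0)
        ens = aremodel.bootstrap_ensemble(X, y, "random_forest",
                                          {"n_estimators": 10}, B=5, seed=2)
        out = aremodel.predict_are(ens, X[:10])
        assert np.allclose(out["mean"], 42.0)
        assert np.allclose(out["sd"], 0.0)

    def test_mean_is_member_mean_and_order_invariant(self, study, ensemble):
        X = study["X_test"].to_numpy()[:20]
        preds = ensemble.member_predictions(X)
        out = aremodel.predict_are(ensemble, X)
        np.testing.assert_allclose(out["mean"], preds.mean(axis=0), atol=1e-12)
        shuffled = aremodel.BootstrapEnsemble(list(reversed(ensemble.members)))
        out2 = aremodel.predict_are(shuffled, X)
        np.testing.assert_allclose(out["mean"], out2["mean"], atol=1e-12)

    def test_member_predictions_clipped_before_aggregation(self):
        ens = aremodel.BootstrapEnsemble([_Const(107.0), _Const(-3.0)])
        X = np.zeros((4, 2))
        preds = ens.member_predictions(X)
        assert set(np.unique(preds)) == {0.0, 100.0}  # 107 -> 100, -3 -> 0
        out = aremodel.predict_are(ens, X)
        assert np.allclose(out["mean"], 50.0)  # (100 + 0) / 2
        assert (out["ci_low"] >= 0).all() and (out["ci_high"] <= 100).all()

    def test_ci_brackets_mean(self, study, ensemble):
        out = aremodel.predict_are(ensemble, study["X_test"].to_numpy())
        assert (out["ci_low"] <= out["mean"] + 1e-12).all()
        assert (out["mean"] <= out["ci_high"] + 1e-12).all()

    def test_invalid_b(self, study):
        with pytest.raises(ValueError):
            aremodel.bootstrap_ensemble(
                study["X_train"].to_numpy(), study["y_train"], "knn", {}, B=0
            )

    def test_reproducible(self, study):
        kwargs = dict(family="xgboost",
                      params={"n_estimators": 20, "max_depth": 2},
                      B=3, seed=11)
        e1 = aremodel.bootstrap_ensemble(study["X_train"].to_numpy(), study["y_train"], **kwargs)
        e2 = aremodel.bootstrap_ensemble(study["X_train"].to_numpy(), study["y_train"], **kwargs)
        X = study["X_test"].to_numpy()[:5]
        np.testing.assert_array_equal(
            e1.member_predictions(X), e2.member_predictions(X)
        )


class TestValidations:
    def test_shuffle_separates_signal_from_noise(self, study, tournament):
        drops = aremodel.validate_shuffle(
            tournament["best"].model, study["X_test"], study["y_test"],
            seed=0, repeats=5,
            column_groups=study["transform"].column_groups(),
        )
        # depth and aspect ratio carry no signal in the response surface
        assert abs(drops["depth"]) < 0.05
        assert abs(drops["aspect_ratio"]) < 0.05
        # antibiotic concentration is the dominant driver
        assert drops["antibiotic_conc"] > 0.1

    def test_external_validation_error_structure(self, study, ensemble):
        val = synthgen.gen_independent_validation(40, 1)
        Xv = prep.apply_transform(val, study["transform"])
        errors, summary = aremodel.validate_external(ens := ensemble, Xv, val[TARGET])
        assert len(errors) == 40
        assert summary["mean_abs_error"] < 15.0  # within the credibility bound
        assert summary["max_abs_error"] >= summary["mean_abs_error"]

    def test_perfect_predictions_give_zero_error(self):
        ens = aremodel.BootstrapEnsemble([_Const(42.0)])
        errors, summary = aremodel.validate_external(
            ens, np.zeros((5, 2)), np.full(5, 42.0)
        )
        assert np.allclose(errors, 0.0) and summary["mean_abs_error"] == 0.0
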