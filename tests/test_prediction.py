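"""Predictor assembly, CV folds, the cross-validated R², and leakage audits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import proteorate as pr
from proteorate.io import AnnotationMap, ConditionDesign, ExpressionMatrix, RateTable
from proteorate.prediction import (
    CVScheme,
    PredictorScale,
    SkipReaction,
    build_predictors,
    cross_validated_predict,
    cv_r2,
    fit_outer_fold,
    make_folds,
)


def _design(n, media=None, growth=None):
    ids = [f"c{i}" for i in range(n)]
    return ConditionDesign(
        pd.DataFrame(
            {
                "media_type": media or ["m1"] * n,
                "growth_rate": growth or [0.1 * (i + 1) for i in range(n)],
            },
            index=pd.Index(ids, name="condition_id"),
        )
    )


def _expr(n_prot, n_cond, rng, prefix="P"):
    return ExpressionMatrix(
        pd.DataFrame(
            rng.lognormal(size=(n_prot, n_cond)),
            index=[f"{prefix}{i}" for i in range(n_prot)],
            columns=[f"c{i}" for i in range(n_cond)],
        )
    )


class TestBuildPredictors:
    def _ann(self, members):
        return AnnotationMap(
            reaction_to_proteins={"R1": frozenset({"P0"})},
            protein_to_subsystems={p: frozenset({"S"}) for p in members},
            reaction_to_subsystem={"R1": "S"},
        )

    def test_subsystem_of_five_is_skipped(self, rng):
        expr = _expr(8, 4, rng)
        ann = self._ann([f"P{i}" for i in range(5)])
        with pytest.raises(SkipReaction) as exc:
            build_predictors("R1", PredictorScale("subsystem"), expr, ann)
        assert exc.value.reason == "SUBSYSTEM_TOO_SMALL"

    def test_subsystem_of_six_is_included(self, rng):
        expr = _expr(8, 4, rng)
        ann = self._ann([f"P{i}" for i in range(6)])
        X = build_predictors("R1", PredictorScale("subsystem"), expr, ann)
        assert X.shape == (4, 6)

    def test_unquantified_members_do_not_count(self, rng):
        # six annotated but only five quantified -> still below threshold
        expr = _expr(5, 4, rng)
        ann = self._ann([f"P{i}" for i in range(5)] + ["P_UNQUANTIFIED"])
        with pytest.raises(SkipReaction):
            build_predictors("R1", PredictorScale("subsystem"), expr, ann)

    def test_proteome_scale_uses_every_protein(self, rng):
        expr = _expr(200, 4, rng)
        X = build_predictors("R1", PredictorScale("proteome"), expr, self._ann(["P0"]))
        assert X.shape == (4, 200)

    def test_focal_requires_bidirectional_uniqueness(self, rng):
        expr = _expr(3, 4, rng)
        ann = AnnotationMap(
            reaction_to_proteins={"R1": frozenset({"P0"}), "R2": frozenset({"P0"})},
            protein_to_subsystems={},
            reaction_to_subsystem={},
        )
        with pytest.raises(SkipReaction) as exc:
            build_predictors("R1", PredictorScale("focal"), expr, ann)
        assert exc.value.reason == "NOT_ONE_TO_ONE"

    def test_focal_is_log2_of_the_unique_protein(self, rng):
        expr = _expr(3, 4, rng)
        ann = AnnotationMap(
            reaction_to_proteins={"R1": frozenset({"P1"})},
            protein_to_subsystems={},
            reaction_to_subsystem={},
        )
        X = build_predictors("R1", PredictorScale("focal"), expr, ann)
        np.testing.assert_allclose(X["P1"], np.log2(expr.data.loc["P1"]))

    def test_subsystem_mean_coarse_grains(self, rng):
        expr = _expr(6, 4, rng)
        ann = AnnotationMap(
            reaction_to_proteins={"R1": frozenset({"P0"})},
            protein_to_subsystems={
                "P0": frozenset({"A"}), "P1": frozenset({"A"}),
                "P2": frozenset({"B"}), "P3": frozenset({"B"}),
            },
            reaction_to_subsystem={"R1": "A"},
        )
        X = build_predictors("R1", PredictorScale("subsystem_mean"), expr, ann)
        assert list(X.columns) == ["A", "B"]
        np.testing.assert_allclose(
            X["A"], np.log2(expr.data.loc[["P0", "P1"]]).mean(axis=0)
        )


class TestMakeFolds:
    def test_leave_media_out_partitions_by_media(self):
        design = _design(
            25,
            media=[m for m in ["a", "b", "c", "d", "e"] for _ in range(5)],
            growth=[0.1 * (i % 5 + 1) for i in range(25)],
        )
        folds = make_folds(design, CVScheme("leave_media_out"))
        assert len(folds) == 5
        assert all(len(test) == 5 for _, test in folds)
        covered = sorted(c for _, test in folds for c in test)
        assert covered == sorted(design.condition_ids)

    def test_leave_growth_rate_out_groups_exact_values(self):
        design = _design(
            6, media=["a", "a", "a", "b", "b", "b"], growth=[0.1, 0.2, 0.3, 0.1, 0.2, 0.3]
        )
        folds = make_folds(design, CVScheme("leave_growth_rate_out"))
        assert len(folds) == 3
        assert all(len(test) == 2 for _, test in folds)

    def test_leave_n_out_seeded_and_reproducible(self):
        design = _design(25)
        scheme = CVScheme("leave_n_out", n_out=2, iterations=100, seed=5)
        folds_a = make_folds(design, scheme)
        folds_b = make_folds(design, scheme)
        assert folds_a == folds_b
        assert len(folds_a) == 100
        assert all(len(t) == 2 and len(set(t)) == 2 for _, t in folds_a)

    def test_leave_one_out_fold_count(self):
        folds = make_folds(_design(8), CVScheme("leave_one_out"))
        assert len(folds) == 8
        assert all(len(t) == 1 for _, t in folds)

    def test_n_out_must_leave_training_data(self):
        with pytest.raises(ValueError, match="n_out"):
            make_folds(_design(3), CVScheme("leave_n_out", n_out=3))

    def test_single_media_cannot_leave_media_out(self):
        with pytest.raises(ValueError, match="media"):
            make_folds(_design(4), CVScheme("leave_media_out"))


class TestCvR2:
    def test_perfect_prediction(self):
        assert cv_r2(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])) == 1.0

    def test_mean_prediction_scores_zero(self):
        assert cv_r2(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0])) == 0.0

    def test_anti_prediction_is_negative(self):
        # SSE=8, SST=2 -> R2 = -3
        assert cv_r2(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])) == -3.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_affine_invariance(self, a, b):
        obs = np.array([1.0, 2.5, 3.0, 4.5])
        pred = np.array([1.2, 2.0, 3.3, 4.1])
        assert cv_r2(a * obs + b, a * pred + b) == pytest.approx(cv_r2(obs, pred), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cv_r2(np.ones(4), np.arange(4.0))


class TestLooOlsOracle:
    """6-condition fixture: pooled LOO predictions vs brute-force enumeration."""

    X = pd.DataFrame({"p": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
                     index=[f"c{i}" for i in range(6)])
    y = pd.Series([1.2, 1.9, 3.4, 3.8, 5.3, 5.9], index=X.index)

    def _run(self):
        design = _design(6)
        return cross_validated_predict(
            "R", self.X, self.y, design, CVScheme("leave_one_out"), penalty="none", seed=0
        )

    def test_pooled_equals_fold_by_fold_ols(self):
        res = self._run()
        for i in range(6):
            train = [j for j in range(6) if j != i]
            slope, icept = np.polyfit(self.X.iloc[train, 0], self.y.iloc[train], 1)
            expected = icept + slope * self.X.iloc[i, 0]
            assert res.pooled["pooled_prediction"].iloc[i] == pytest.approx(
                expected, abs=1e-10
            )

    def test_cv_r2_matches_hand_formula(self):
        res = self._run()
        obs = res.pooled["observed"].to_numpy()
        pred = res.pooled["pooled_prediction"].to_numpy()
        by_hand = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert res.cv_r2 == pytest.approx(by_hand, abs=1e-12)

    def test_pooled_matches_press_formula(self):
        """LOO OLS predictions equal the closed-form PRESS residuals."""
        res = self._run()
        A = np.column_stack([np.ones(6), self.X["p"]])
        H = A @ np.linalg.solve(A.T @ A, A.T)
        resid = self.y.to_numpy() - H @ self.y.to_numpy()
        press_pred = self.y.to_numpy() - resid / (1 - np.diag(H))
        np.testing.assert_allclose(
            res.pooled["pooled_prediction"].to_numpy(), press_pred, atol=1e-10
        )


class TestCrossValidatedPredict:
    def test_noiseless_linear_signal_recovered_by_ridge(self, rng):
        n = 10
        X = pd.DataFrame(rng.normal(size=(n, 3)), index=[f"c{i}" for i in range(n)],
                         columns=list("abc"))
        y = pd.Series(3.0 * X["b"].to_numpy() + 2.0, index=X.index)
        res = cross_validated_predict(
            "R", X, y, _design(n), CVScheme("leave_one_out"), penalty="ridge", seed=0
        )
        assert res.cv_r2 >= 0.99

    def test_single_spike_rate_skipped_under_media_cv(self, rng):
        # rate zero except in one condition: some training folds are constant
        design = _design(6, media=["a", "a", "b", "b", "c", "c"],
                         growth=[0.1, 0.2, 0.1, 0.2, 0.1, 0.2])
        X = pd.DataFrame(rng.normal(size=(6, 2)), index=design.condition_ids)
        y = pd.Series([0.0, 0.0, 0.0, 0.0, 0.0, 7.5], index=design.condition_ids)
        res = cross_validated_predict(
            "R", X, y, design, CVScheme("leave_media_out"), penalty="ridge", seed=0
        )
        assert res.skipped and res.reason == "CONSTANT_RESPONSE"

    def test_wholly_constant_rate_skipped(self, rng):
        design = _design(5)
        X = pd.DataFrame(rng.normal(size=(5, 2)), index=design.condition_ids)
        y = pd.Series(np.ones(5), index=design.condition_ids)
        res = cross_validated_predict(
            "R", X, y, design, CVScheme("leave_one_out"), penalty="ridge", seed=0
        )
        assert res.skipped and res.reason == "CONSTANT_RESPONSE"

    def test_leakage_audit_refit_is_bit_identical(self, small_dataset):
        """Deleting held-out conditions from all inputs reproduces each
        outer-fold model's coefficients exactly."""
        d = small_dataset
        m = pr.RatePredictionModel(d.expression, d.rates, d.design, d.annotations)
        res = m.fit(
            scheme=CVScheme("leave_n_out", n_out=2, iterations=6),
            scales=("proteome",), seed=3,
        )
        checked = 0
        for r in res.results[:2]:
            if r.skipped:
                continue
            X_full = build_predictors(
                r.reaction_id, PredictorScale("proteome"), d.expression, d.annotations
            ).loc[d.design.condition_ids]
            for i, meta in enumerate(r.folds[:3]):
                keep = [c for c in d.design.condition_ids if c not in meta["test_ids"]]
                # physically delete the held-out conditions from every input
                expr_red = ExpressionMatrix(d.expression.data[keep])
                X_red = build_predictors(
                    r.reaction_id, PredictorScale("proteome"), expr_red, d.annotations
                ).loc[keep]
                y_red = d.rates.data.loc[r.reaction_id, keep].to_numpy()
                model, _ = fit_outer_fold(X_red, y_red, "ridge", None, meta["inner_seed"])
                np.testing.assert_array_equal(
                    model.coefficients.to_numpy(),
                    r.coefficients.iloc[i].to_numpy(),
                )
                checked += 1
        assert checked >= 3

    def test_zscored_display_mode_marks_results_and_keeps_focal_r2(self, small_dataset):
        d = small_dataset
        m = pr.RatePredictionModel(d.expression, d.rates, d.design, d.annotations)
        scheme = CVScheme("leave_n_out", n_out=2, iterations=5)
        raw = m.fit(scheme=scheme, scales=("focal",), seed=1)
        z = m.fit(scheme=scheme, scales=("focal",), seed=1, zscore_predictors=True)
        assert all(r.zscored_predictors for r in z.results)
        # OLS predictions are invariant to affine predictor rescaling
        for a, b in zip(raw.results, z.results):
            if not a.skipped:
                assert b.cv_r2 == pytest.approx(a.cv_r2, rel=1e-9)


class TestNoiseMonotonicity:
    def test_more_expression_noise_means_worse_prediction(self):
        medians = []
        for noise in (0.1, 0.25, 0.5):
            d = pr.generate_dataset(pr.GeneratorConfig(noise_sd_log2=noise, seed=0))
            m = pr.RatePredictionModel(d.expression, d.rates, d.design, d.annotations)
            res = m.fit(
                scheme=CVScheme("leave_n_out", n_out=2, iterations=30),
                scales=("proteome",), seed=0,
            )
            medians.append(res.median_cv_r2("proteome"))
        assert medians[0] >= medians[1] - 0.02
        assert medians[1] >= medians[2] - 0.02


class TestRunAllScales:
    def test_result_cardinality_with_two_penalties(self, small_dataset):
        d = small_dataset
        res = pr.run_all_scales(
            d.expression, d.rates, d.design, d.annotations,
            CVScheme("leave_n_out", n_out=2, iterations=3),
            scales=("proteome",), penalties=("ridge", "lasso"), seed=0,
        )
        assert len(res) == 2 * len(d.rates.reaction_ids)

    def test_missing_subsystem_annotation_skips_quietly(self, rng):
        expr = _expr(4, 5, rng)
        rates = RateTable(
            pd.DataFrame(rng.normal(size=(1, 5)), index=["R1"],
                         columns=[f"c{i}" for i in range(5)])
        )
        ann = AnnotationMap(
            reaction_to_proteins={"R1": frozenset({"P0"})},
            protein_to_subsystems={},
            reaction_to_subsystem={},
        )
        res = pr.run_all_scales(
            expr, rates, _design(5), ann, CVScheme("leave_one_out"),
            scales=("subsystem", "focal"), seed=0,
        )
        by_scale = {r.scale: r for r in res}
        assert by_scale["subsystem"].skipped
        assert by_scale["subsystem"].reason == "SUBSYSTEM_TOO_SMALL"
        assert not by_scale["focal"].skipped
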