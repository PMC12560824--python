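"""Cross-validated rate prediction at three proteome scales.

Stage 2 of the pipeline. For each reaction, a predictor table is assembled
at one of four scales — the focal enzyme alone, all quantified proteins of
the reaction's pathway subsystem, the whole proteome, or one mean column per
subsystem (a coarse-grained proteome) — always as log₂ abundances. An outer
cross-validation loop (leave-n-out, leave-media-out, leave-growth-rate-out,
or leave-one-out) fits a penalized linear model on the training conditions
only, with λ chosen by inner ~10-fold CV; held-out predictions are pooled
per condition by arithmetic mean across iterations and scored with the
cross-validated coefficient of determination R² = 1 − SSE/SST, which may be
negative when the model predicts worse than the observed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    ConditionDesign,
    ExpressionMatrix,
    RateTable,
    log2_transform,
    zscore_by_protein,
)
from .linear_model import (
    ConstantResponseError,
    LambdaPath,
    PenalizedLinearModel,
    fit,
    fit_with_lambda_cv,
    predict,
)

__all__ = [
    "PredictorScale",
    "CVScheme",
    "PredictionResult",
    "SkipReaction",
    "build_predictors",
    "make_folds",
    "cross_validated_predict",
    "cv_r2",
    "run_all_scales",
]

SCALES = ("focal", "subsystem", "proteome", "subsystem_mean")


class SkipReaction(Exception):
    """A reaction×scale combination cannot be modelled; carries a reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class PredictorScale:
    """Which slice of the proteome predicts a reaction.

    ``min_subsystem_size`` is the smallest admissible number of quantified
    proteins in a subsystem (default 6: a pathway must have *more than five*
    quantified members to support the within-pathway models).
    """

    scale: str
    min_subsystem_size: int = 6

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")


@dataclass(frozen=True)
class CVScheme:
    """Outer cross-validation design."""

    kind: str  # leave_n_out | leave_media_out | leave_growth_rate_out | leave_one_out
    n_out: int = 2
    iterations: int = 100
    seed: int = 0

    _KINDS = ("leave_n_out", "leave_media_out", "leave_growth_rate_out", "leave_one_out")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"cv kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.kind == "leave_n_out" and (self.n_out < 1 or self.iterations < 1):
            raise ValueError("leave_n_out needs n_out >= 1 and iterations >= 1")


@dataclass
class PredictionResult:
    """Per-reaction out-of-fold predictions, cv R² and coefficient draws."""

    reaction_id: str
    scale: str
    penalty: str
    cv_kind: str
    n_predictors: int = 0
    pooled: pd.DataFrame | None = None  # condition_id, observed, pooled_prediction, n_times_held_out
    cv_r2: float | None = None
    cv_r2_fold_sse: float | None = None  # alternative pooling: SSE summed per fold prediction
    coefficients: pd.DataFrame | None = None  # iterations × predictors, original scale
    intercepts: np.ndarray | None = None
    chosen_lambdas: np.ndarray | None = None
    folds: list[dict] = field(default_factory=list)  # test_ids + inner_seed per outer fold
    skipped: bool = False
    reason: str | None = None
    zscored_predictors: bool = False  # coefficient-display mode marker


def _derive_seed(seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2³¹ from a user seed and a stream key."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Predictor assembly
# ---------------------------------------------------------------------------


def _focal_protein(reaction_id: str, ann: AnnotationMap) -> str:
    prots = ann.reaction_to_proteins.get(reaction_id, frozenset())
    if len(prots) != 1:
        raise SkipReaction("NOT_ONE_TO_ONE", f"{reaction_id} maps to {len(prots)} proteins")
    (pid,) = prots
    partners = {r for r, ps in ann.reaction_to_proteins.items() if pid in ps}
    if partners != {reaction_id}:
        raise SkipReaction(
            "NOT_ONE_TO_ONE", f"protein {pid} also maps to {sorted(partners - {reaction_id})}"
        )
    return pid


def build_predictors(
    reaction_id: str,
    scale: PredictorScale,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    log2_expr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Conditions × predictors table of log₂ abundances for one reaction.

    Raises :class:`SkipReaction` when the scale is not applicable (reaction
    not 1:1 for the focal scale; subsystem with five or fewer quantified
    proteins for the subsystem scale).
    """
    L = log2_expr if log2_expr is not None else log2_transform(expr)
    if scale.scale == "focal":
        pid = _focal_protein(reaction_id, ann)
        if pid not in L.index:
            raise SkipReaction("NOT_ONE_TO_ONE", f"focal protein {pid} not quantified")
        return L.loc[[pid]].T
    if scale.scale == "subsystem":
        sub = ann.reaction_to_subsystem.get(reaction_id)
        if sub is None:
            raise SkipReaction("SUBSYSTEM_TOO_SMALL", f"{reaction_id} has no subsystem")
        members = sorted(ann.subsystem_members(sub) & set(L.index))
        if len(members) < scale.min_subsystem_size:
            raise SkipReaction(
                "SUBSYSTEM_TOO_SMALL",
                f"{sub} has {len(members)} quantified proteins "
                f"(needs >= {scale.min_subsystem_size})",
            )
        return L.loc[members].T
    if scale.scale == "proteome":
        return L.T
    # subsystem_mean: one coarse-grained column per subsystem
    cols = {}
    for sub in ann.subsystems:
        members = sorted(ann.subsystem_members(sub) & set(L.index))
        if members:
            cols[sub] = L.loc[members].mean(axis=0)
    if not cols:
        raise SkipReaction("SUBSYSTEM_TOO_SMALL", "no subsystem has quantified members")
    return pd.DataFrame(cols, index=L.columns)


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def make_folds(
    design: ConditionDesign, scheme: CVScheme, seed: int | None = None
) -> list[tuple[list[str], list[str]]]:
    """Outer (train, test) condition splits for the scheme.

    leave_media_out holds out every condition of one media type per fold;
    leave_growth_rate_out holds out all media at one exact dilution rate.
    leave_n_out draws ``iterations`` seeded random test sets of size n_out
    without replacement within each iteration.
    """
    conds = design.condition_ids
    n = len(conds)
    if scheme.kind == "leave_one_out":
        return [([c for c in conds if c != t], [t]) for t in conds]
    if scheme.kind == "leave_n_out":
        if scheme.n_out >= n:
            raise ValueError(f"n_out={scheme.n_out} must be < n_conditions={n}")
        rng = np.random.default_rng(seed if seed is not None else scheme.seed)
        folds = []
        for _ in range(scheme.iterations):
            test = sorted(rng.choice(n, size=scheme.n_out, replace=False))
            test_ids = [conds[i] for i in test]
            folds.append(([c for c in conds if c not in test_ids], test_ids))
        return folds
    if scheme.kind == "leave_media_out":
        media = design.media_types
        if len(media) < 2:
            raise ValueError("leave_media_out needs at least 2 media types")
        folds = []
        for m in media:
            test_ids = [c for c in conds if design.table.loc[c, "media_type"] == m]
            folds.append(([c for c in conds if c not in test_ids], test_ids))
        return folds
    # leave_growth_rate_out: group by exact growth-rate equality
    rates = design.table["growth_rate"]
    levels = sorted(set(rates))
    if len(levels) < 2:
        raise ValueError("leave_growth_rate_out needs at least 2 distinct growth rates")
    folds = []
    for g in levels:
        test_ids = [c for c in conds if rates.loc[c] == g]
        folds.append(([c for c in conds if c not in test_ids], test_ids))
    return folds


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def cv_r2(observed: np.ndarray, pooled_predictions: np.ndarray) -> float:
    """1 − SSE/SST with SSE from out-of-training predictions only.

    SST uses the observations themselves. Negative values are legal: the
    model then explains less than the observed mean would.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(pooled_predictions, float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values have zero variance; R2 undefined")
    sse = float(((obs - pred) ** 2).sum())
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# Outer CV driver
# ---------------------------------------------------------------------------


def fit_outer_fold(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    penalty: str,
    path: LambdaPath | None,
    inner_seed: int,
) -> tuple[PenalizedLinearModel, float | None]:
    """One outer fold's model, fit on training conditions only.

    Exposed separately so a leakage audit can replay any fold from inputs
    with the held-out conditions physically removed.
    """
    if np.ptp(y_train) == 0:
        raise ConstantResponseError("constant response in training fold")
    if penalty == "none":
        return fit(X_train, y_train, penalty="none"), None
    model, lam = fit_with_lambda_cv(X_train, y_train, penalty=penalty, path=path, seed=inner_seed)
    return model, lam


def cross_validated_predict(
    reaction_id: str,
    predictors: pd.DataFrame,
    y: pd.Series,
    design: ConditionDesign,
    scheme: CVScheme,
    penalty: str = "ridge",
    path: LambdaPath | None = None,
    seed: int = 0,
    scale: str = "",
) -> PredictionResult:
    """Outer CV for one reaction: fit per fold, pool, score.

    The outer-fold seed and every fold's inner-CV seed derive
    deterministically from ``seed``. A constant training response in any
    fold skips the whole reaction×scheme with reason CONSTANT_RESPONSE.
    """
    conds = list(predictors.index)
    if list(y.index) != conds:
        y = y.loc[conds]
    folds = make_folds(design, scheme, seed=_derive_seed(seed, 0))

    base = PredictionResult(
        reaction_id=reaction_id, scale=scale, penalty=penalty, cv_kind=scheme.kind,
        n_predictors=predictors.shape[1],
    )
    if np.ptp(y.to_numpy()) == 0:
        return replace(base, skipped=True, reason="CONSTANT_RESPONSE")

    pred_sums = pd.Series(0.0, index=conds)
    pred_counts = pd.Series(0, index=conds)
    coef_rows, intercepts, lams, fold_meta = [], [], [], []
    fold_sse = 0.0
    fold_obs: list[float] = []
    try:
        for i, (train_ids, test_ids) in enumerate(folds):
            inner_seed = _derive_seed(seed, 1, i)
            model, lam = fit_outer_fold(
                predictors.loc[train_ids], y.loc[train_ids].to_numpy(), penalty, path, inner_seed
            )
            yhat = predict(model, predictors.loc[test_ids])
            pred_sums.loc[test_ids] += yhat
            pred_counts.loc[test_ids] += 1
            fold_sse += float(((y.loc[test_ids].to_numpy() - yhat) ** 2).sum())
            fold_obs.extend(y.loc[test_ids].tolist())
            coef_rows.append(model.coefficients)
            intercepts.append(model.intercept)
            lams.append(np.nan if lam is None else lam)
            fold_meta.append({"test_ids": tuple(test_ids), "inner_seed": inner_seed})
    except ConstantResponseError:
        return replace(base, skipped=True, reason="CONSTANT_RESPONSE")

    held = pred_counts > 0
    pooled = pd.DataFrame(
        {
            "observed": y[held],
            "pooled_prediction": pred_sums[held] / pred_counts[held],
            "n_times_held_out": pred_counts[held],
        }
    ).rename_axis("condition_id")
    obs = pooled["observed"].to_numpy()
    if pooled.shape[0] < 3 or np.ptp(obs) == 0:
        return replace(base, skipped=True, reason="CONSTANT_RESPONSE")
    r2 = cv_r2(obs, pooled["pooled_prediction"].to_numpy())
    fo = np.asarray(fold_obs)
    sst_fold = float(((fo - fo.mean()) ** 2).sum())
    r2_fold = 1.0 - fold_sse / sst_fold if sst_fold > 0 else None

    return replace(
        base,
        pooled=pooled,
        cv_r2=r2,
        cv_r2_fold_sse=r2_fold,
        coefficients=pd.DataFrame(coef_rows).reset_index(drop=True),
        intercepts=np.asarray(intercepts),
        chosen_lambdas=np.asarray(lams),
        folds=fold_meta,
    )


def run_all_scales(
    expr: ExpressionMatrix,
    rates: RateTable,
    design: ConditionDesign,
    ann: AnnotationMap,
    scheme: CVScheme,
    scales: tuple[str, ...] = ("focal", "subsystem", "proteome"),
    penalties: tuple[str, ...] = ("ridge",),
    min_subsystem_size: int = 6,
    path: LambdaPath | None = None,
    seed: int = 0,
    zscore_predictors: bool = False,
) -> list[PredictionResult]:
    """Every reaction × scale × penalty, with skip flags instead of aborts.

    The focal scale always uses ordinary least squares (a single predictor
    needs no penalty); wider scales use each requested penalty.

    ``zscore_predictors`` additionally z-scores each protein's log₂
    abundances globally across all conditions before modelling — the
    coefficient-display convention that makes β magnitudes comparable
    between proteins. Predictive CV runs leave it off (standardization then
    happens inside each training fold only, so nothing global leaks); the
    mode is recorded on every result.
    """
    design.validate_against(expr, rates)
    ann.validate_against(rates, expr)
    L = log2_transform(expr)
    if zscore_predictors:
        L = zscore_by_protein(L)
    results: list[PredictionResult] = []
    scale_idx = {s: i for i, s in enumerate(SCALES)}
    pen_idx = {"none": 0, "ridge": 1, "lasso": 2}
    for si, scale_name in enumerate(scales):
        ps = PredictorScale(scale_name, min_subsystem_size=min_subsystem_size)
        use_pens = ("none",) if scale_name == "focal" else penalties
        for ri, rid in enumerate(rates.reaction_ids):
            y = rates.data.loc[rid, design.condition_ids]
            for pen in use_pens:
                run_seed = _derive_seed(seed, scale_idx[scale_name], ri, pen_idx[pen])
                try:
                    X = build_predictors(rid, ps, expr, ann, log2_expr=L).loc[
                        design.condition_ids
                    ]
                except SkipReaction as sk:
                    results.append(
                        PredictionResult(
                            reaction_id=rid, scale=scale_name, penalty=pen,
                            cv_kind=scheme.kind, skipped=True, reason=sk.reason,
                        )
                    )
                    continue
                results.append(
                    cross_validated_predict(
                        rid, X, y, design, scheme, penalty=pen, path=path,
                        seed=run_seed, scale=scale_name,
                    )
                )
    for r in results:
        r.zscored_predictors = zscore_predictors
    return results
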