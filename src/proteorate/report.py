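"""Stage 3: distribution summaries, coefficient stability, sparsity, and
growth-decoupling diagnostics over a collection of prediction results."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariation import pearson
from .io import ConditionDesign, RateTable
from .prediction import PredictionResult

__all__ = [
    "summarize",
    "coefficient_stability",
    "lasso_sparsity",
    "growth_decoupling",
    "results_frame",
    "predictions_frame",
    "coefficients_frame",
]

log = logging.getLogger("proteorate")

_QUANTS = (0.05, 0.25, 0.75, 0.95)


def summarize(results: list[PredictionResult]) -> pd.DataFrame:
    """Median and 5/25/75/95th cv-R² quantiles per (scale, penalty, scheme).

    Quantiles use linear interpolation between order statistics; skipped
    reactions are counted separately, and groups where everything was
    skipped are omitted with a log entry.
    """
    rows = []
    groups: dict[tuple[str, str, str], list[PredictionResult]] = {}
    for r in results:
        groups.setdefault((r.scale, r.penalty, r.cv_kind), []).append(r)
    for (scale, pen, kind), grp in groups.items():
        vals = np.array([r.cv_r2 for r in grp if not r.skipped and r.cv_r2 is not None])
        n_skipped = sum(r.skipped for r in grp)
        if vals.size == 0:
            log.info("summary group (%s, %s, %s) entirely skipped; omitted", scale, pen, kind)
            continue
        q = np.quantile(vals, _QUANTS)
        rows.append(
            {
                "scale": scale, "penalty": pen, "cv_scheme": kind,
                "n_reactions": len(grp), "n_skipped": n_skipped,
                "median_cv_r2": float(np.median(vals)),
                "q05": q[0], "q25": q[1], "q75": q[2], "q95": q[3],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scale", "penalty", "cv_scheme", "n_reactions", "n_skipped",
            "median_cv_r2", "q05", "q25", "q75", "q95",
        ],
    )


def coefficient_stability(result: PredictionResult) -> pd.DataFrame:
    """Mean and sd (n−1) of each coefficient across outer CV iterations.

    The intercept is excluded from the display. A single iteration leaves
    the sd undefined (NaN) and is flagged in the ``sd_defined`` column.
    """
    if result.skipped or result.coefficients is None:
        raise ValueError(f"{result.reaction_id}: no fitted coefficients (skipped result)")
    C = result.coefficients
    sd_ok = len(C) >= 2
    out = pd.DataFrame(
        {
            "mean_beta": C.mean(axis=0),
            "sd_beta": C.std(axis=0, ddof=1) if sd_ok else np.nan,
            "frac_nonzero": (C != 0).mean(axis=0),
        }
    ).rename_axis("predictor_id")
    out["sd_defined"] = sd_ok
    return out


@dataclass
class SparsitySummary:
    reaction_id: str
    nonzero_counts: np.ndarray  # per outer iteration
    iqr: tuple[float, float]  # 25th-75th quantiles of the counts


def lasso_sparsity(results: list[PredictionResult]) -> list[SparsitySummary]:
    """Non-zero coefficient counts per outer iteration, for lasso fits only.

    The exact-zero test is legitimate: coordinate descent soft-thresholds
    coefficients to exactly 0. Ridge results yield an empty list with a log
    note (ridge never zeroes a coefficient exactly).
    """
    out = []
    for r in results:
        if r.penalty != "lasso" or r.skipped or r.coefficients is None:
            continue
        counts = (r.coefficients != 0).sum(axis=1).to_numpy()
        q25, q75 = np.quantile(counts, [0.25, 0.75])
        out.append(SparsitySummary(r.reaction_id, counts, (float(q25), float(q75))))
    if not out:
        log.info("no lasso results present; sparsity summary is empty")
    return out


def growth_decoupling(
    rates: RateTable,
    design: ConditionDesign,
    results: list[PredictionResult],
    scale: str = "proteome",
) -> pd.DataFrame:
    """Pearson(rate, growth rate) joined with each reaction's cv R².

    Exposes reactions whose rate is uncorrelated with growth yet still
    predictable from proteome composition — rate information beyond the
    global growth signal. Zero-variance rates are flagged and excluded from
    the correlation (not fabricated as 0).
    """
    g = design.table.loc[rates.condition_ids, "growth_rate"].to_numpy()
    r2 = {
        r.reaction_id: r.cv_r2
        for r in results
        if r.scale == scale and not r.skipped and r.cv_r2 is not None
    }
    rows = []
    for rid in rates.reaction_ids:
        v = rates.data.loc[rid].to_numpy()
        if np.ptp(v) == 0:
            rows.append({"reaction_id": rid, "pearson_with_growth": np.nan,
                         "cv_r2": r2.get(rid), "flag": "ZERO_VARIANCE"})
            continue
        r, _ = pearson(v, g)
        rows.append({"reaction_id": rid, "pearson_with_growth": r,
                     "cv_r2": r2.get(rid), "flag": ""})
    return pd.DataFrame(rows, columns=["reaction_id", "pearson_with_growth", "cv_r2", "flag"])


# ---------------------------------------------------------------------------
# Tidy frames for on-disk output
# ---------------------------------------------------------------------------


def results_frame(results: list[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reaction_id": r.reaction_id, "scale": r.scale, "penalty": r.penalty,
                "cv_scheme": r.cv_kind, "n_predictors": r.n_predictors,
                "cv_r2": r.cv_r2, "cv_r2_fold_sse": r.cv_r2_fold_sse,
                "skipped": r.skipped, "reason": r.reason or "",
            }
            for r in results
        ]
    )


def predictions_frame(results: list[PredictionResult]) -> pd.DataFrame:
    frames = []
    for r in results:
        if r.skipped or r.pooled is None:
            continue
        f = r.pooled.reset_index()
        f.insert(0, "reaction_id", r.reaction_id)
        f.insert(1, "scale", r.scale)
        f.insert(2, "penalty", r.penalty)
        frames.append(f)
    if not frames:
        return pd.DataFrame(
            columns=["reaction_id", "scale", "penalty", "condition_id",
                     "observed", "pooled_prediction", "n_times_held_out"]
        )
    return pd.concat(frames, ignore_index=True)


def coefficients_frame(results: list[PredictionResult]) -> pd.DataFrame:
    frames = []
    for r in results:
        if r.skipped or r.coefficients is None:
            continue
        stab = coefficient_stability(r).reset_index()
        stab.insert(0, "reaction_id", r.reaction_id)
        stab.insert(1, "scale", r.scale)
        stab.insert(2, "penalty", r.penalty)
        frames.append(stab.drop(columns="sd_defined"))
    if not frames:
        return pd.DataFrame(
            columns=["reaction_id", "scale", "penalty", "predictor_id",
                     "mean_beta", "sd_beta", "frac_nonzero"]
        )
    return pd.concat(frames, ignore_index=True)
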