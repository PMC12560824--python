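"""Model/Results facade over the prediction pipeline.

:class:`RatePredictionModel` binds a dataset (expression, rates, design,
annotations); :meth:`~RatePredictionModel.fit` runs the cross-validated
prediction stage at the requested scales/penalties and returns a
:class:`RatePredictionResults` carrying per-reaction cv R² values,
coefficient draws and diagnostics, with a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import report
from .covariation import CovariationTable, covariation_table, extract_focal_pairs
from .io import (
    AnnotationMap,
    ConditionDesign,
    ExpressionMatrix,
    RateTable,
    read_annotations,
    read_conditions,
    read_matrix,
)
from .linear_model import LambdaPath
from .prediction import CVScheme, PredictionResult, run_all_scales

__all__ = ["RatePredictionModel", "RatePredictionResults"]


@dataclass
class RatePredictionModel:
    """Reaction rates modelled as penalized linear functions of log₂ abundances."""

    expression: ExpressionMatrix
    rates: RateTable
    design: ConditionDesign
    annotations: AnnotationMap

    def __post_init__(self) -> None:
        self.design.validate_against(self.expression, self.rates)
        self.annotations.validate_against(self.rates, self.expression)
        if set(self.expression.condition_ids) != set(self.rates.condition_ids):
            raise ValueError("expression and rate tables cover different conditions")

    @classmethod
    def from_files(
        cls,
        expression: str | Path,
        rates: str | Path,
        conditions: str | Path,
        reaction_protein: str | Path,
        subsystems_gmt: str | Path,
        reaction_subsystem: str | Path,
    ) -> "RatePredictionModel":
        return cls(
            expression=read_matrix(expression, "expression"),
            rates=read_matrix(rates, "rate"),
            design=read_conditions(conditions),
            annotations=read_annotations(reaction_protein, subsystems_gmt, reaction_subsystem),
        )

    def covariation(
        self, excluded_conditions: set[str] = frozenset(), k: int = 3
    ) -> CovariationTable:
        """Stage-1 focal-pair covariation statistics."""
        pairs = extract_focal_pairs(
            self.rates, self.expression, self.annotations, excluded_conditions
        )
        return covariation_table(pairs, k=k)

    def fit(
        self,
        scheme: CVScheme | None = None,
        scales: tuple[str, ...] = ("focal", "subsystem", "proteome"),
        penalties: tuple[str, ...] = ("ridge",),
        min_subsystem_size: int = 6,
        path: LambdaPath | None = None,
        seed: int = 0,
        zscore_predictors: bool = False,
    ) -> "RatePredictionResults":
        scheme = scheme or CVScheme(kind="leave_n_out", n_out=2, iterations=100)
        results = run_all_scales(
            self.expression, self.rates, self.design, self.annotations, scheme,
            scales=scales, penalties=penalties,
            min_subsystem_size=min_subsystem_size, path=path, seed=seed,
            zscore_predictors=zscore_predictors,
        )
        return RatePredictionResults(model=self, scheme=scheme, results=results, seed=seed)


@dataclass
class RatePredictionResults:
    """Fitted cross-validation results across reactions and scales."""

    model: RatePredictionModel
    scheme: CVScheme
    results: list[PredictionResult]
    seed: int

    def __iter__(self):
        return iter(self.results)

    def get(self, reaction_id: str, scale: str, penalty: str | None = None) -> PredictionResult:
        for r in self.results:
            if r.reaction_id == reaction_id and r.scale == scale and (
                penalty is None or r.penalty == penalty
            ):
                return r
        raise KeyError((reaction_id, scale, penalty))

    def summary(self) -> pd.DataFrame:
        """Scale-level summary: median cv R² with 5/25/75/95th quantiles."""
        return report.summarize(self.results)

    def summary_text(self) -> str:
        df = self.summary()
        lines = [
            "Cross-validated rate prediction",
            f"  scheme: {self.scheme.kind} (n_out={self.scheme.n_out}, "
            f"iterations={self.scheme.iterations}), seed={self.seed}",
            f"  conditions: {len(self.model.design.condition_ids)}, "
            f"reactions: {len(self.model.rates.reaction_ids)}, "
            f"proteins: {len(self.model.expression.protein_ids)}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)

    def coefficient_stability(self, reaction_id: str, scale: str, penalty: str | None = None):
        return report.coefficient_stability(self.get(reaction_id, scale, penalty))

    def lasso_sparsity(self):
        return report.lasso_sparsity(self.results)

    def growth_decoupling(self, scale: str = "proteome") -> pd.DataFrame:
        return report.growth_decoupling(self.model.rates, self.model.design, self.results, scale)

    def median_cv_r2(self, scale: str, penalty: str | None = None) -> float:
        vals = [
            r.cv_r2
            for r in self.results
            if r.scale == scale and not r.skipped and r.cv_r2 is not None
            and (penalty is None or r.penalty == penalty)
        ]
        if not vals:
            raise ValueError(f"no unskipped results at scale {scale!r}")
        return float(np.median(vals))

    def save(self, out_dir: str | Path) -> None:
        """Write results.tsv, predictions.tsv, coefficients.tsv, summary.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.results_frame(self.results).to_csv(out / "results.tsv", sep="\t", index=False)
        report.predictions_frame(self.results).to_csv(
            out / "predictions.tsv", sep="\t", index=False
        )
        report.coefficients_frame(self.results).to_csv(
            out / "coefficients.tsv", sep="\t", index=False
        )
        self.summary().to_csv(out / "summary.tsv", sep="\t", index=False)

    def plot_observed_vs_predicted(self, reaction_id: str, scale: str, ax=None):
        """Scatter of pooled out-of-fold predictions against observations."""
        import matplotlib.pyplot as plt

        r = self.get(reaction_id, scale)
        if r.skipped or r.pooled is None:
            raise ValueError(f"{reaction_id} at {scale} was skipped ({r.reason})")
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(r.pooled["observed"], r.pooled["pooled_prediction"])
        lo = min(r.pooled["observed"].min(), r.pooled["pooled_prediction"].min())
        hi = max(r.pooled["observed"].max(), r.pooled["pooled_prediction"].max())
        ax.plot([lo, hi], [lo, hi], ls="--", c="grey")
        ax.set_xlabel("observed rate")
        ax.set_ylabel("pooled out-of-fold prediction")
        ax.set_title(f"{reaction_id} ({scale}, {r.penalty}); cv R² = {r.cv_r2:.2f}")
        return ax
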