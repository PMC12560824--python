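"""Single protein-to-rate covariation statistics.

Stage 1 of the pipeline: for every reaction catalysed by exactly one protein
(whose protein in turn maps to exactly one reaction), quantify how the
enzyme's abundance covaries with its reaction rate across conditions, using
Spearman correlation, Pearson correlation with and without a log₂ transform
of the abundances, and a k-nearest-neighbour (Kraskov–Stögbauer–Grassberger)
mutual-information estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma

from .io import AnnotationMap, ExpressionMatrix, RateTable

__all__ = [
    "FocalPair",
    "CovariationResult",
    "extract_focal_pairs",
    "spearman",
    "pearson",
    "mutual_information",
    "covariation_table",
]


@dataclass
class FocalPair:
    """A reaction and its unique catalysing protein, aligned by condition."""

    reaction_id: str
    protein_id: str
    condition_ids: list[str]
    abundances: np.ndarray
    rates: np.ndarray


@dataclass
class CovariationResult:
    """Per-pair covariation statistics; flags mark undefined estimates."""

    reaction_id: str
    protein_id: str
    n_conditions: int
    spearman_rho: float | None
    pearson_r_linear: float | None
    pearson_r_log: float | None
    mutual_information: float | None
    zero_variance_flag: bool
    mi_clipped: bool = False
    mi_tie_warning: bool = False
    flags: list[str] = field(default_factory=list)


def extract_focal_pairs(
    rates: RateTable,
    expr: ExpressionMatrix,
    ann: AnnotationMap,
    excluded_conditions: set[str] | frozenset[str] = frozenset(),
) -> list[FocalPair]:
    """Reactions passing the bidirectional 1:1 reaction↔protein filter.

    A pair is emitted only when the reaction maps to exactly one protein AND
    that protein maps back to exactly that one reaction — the focal-enzyme
    criterion. ``excluded_conditions`` (e.g. auxotroph cultures whose
    genetics could drive the relationship) are dropped from both series.
    """
    known = set(rates.condition_ids)
    unknown = set(excluded_conditions) - known
    if unknown:
        raise ValueError(f"excluded conditions not in the rate table: {sorted(unknown)}")
    kept = [c for c in rates.condition_ids if c not in excluded_conditions]

    protein_to_reactions: dict[str, set[str]] = {}
    for rid, prots in ann.reaction_to_proteins.items():
        for p in prots:
            protein_to_reactions.setdefault(p, set()).add(rid)

    pairs: list[FocalPair] = []
    for rid in rates.reaction_ids:
        prots = ann.reaction_to_proteins.get(rid, frozenset())
        if len(prots) != 1:
            continue
        (pid,) = prots
        if protein_to_reactions.get(pid, set()) != {rid}:
            continue
        if pid not in expr.data.index or not kept:
            continue
        pairs.append(
            FocalPair(
                reaction_id=rid,
                protein_id=pid,
                condition_ids=kept,
                abundances=expr.data.loc[pid, kept].to_numpy(),
                rates=rates.data.loc[rid, kept].to_numpy(),
            )
        )
    return pairs


def _zero_var(x: np.ndarray) -> bool:
    return bool(np.ptp(x) == 0)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float | None, bool]:
    """Spearman rank correlation with average-rank tie handling.

    Returns (rho, zero_variance_flag); rho is None when either rank vector
    is constant (the correlation is undefined, not fabricated as 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors of length >= 3")
    if _zero_var(x) or _zero_var(y):
        return None, True
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.unique(x).size == x.size and np.unique(y).size == y.size:
        # tie-free: the classical formula equals Pearson of the (integer)
        # ranks and is exact, so perfect monotonicity yields exactly +/-1
        n = x.size
        d2 = np.sum((rx - ry) ** 2)
        return float(1.0 - 6.0 * d2 / (n * (n**2 - 1))), False
    rho = stats.pearsonr(rx, ry).statistic
    return float(rho), False


def pearson(
    x: np.ndarray, y: np.ndarray, log_transform_x: bool = False
) -> tuple[float | None, bool]:
    """Product-moment correlation, optionally log₂-transforming x first."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    if log_transform_x:
        if not (x > 0).all():
            raise ValueError("log transform requires strictly positive x")
        x = np.log2(x)
    if _zero_var(x) or _zero_var(y):
        return None, True
    return float(stats.pearsonr(x, y).statistic), False


def mutual_information(
    x: np.ndarray, y: np.ndarray, k: int = 3
) -> tuple[float, bool, bool]:
    """KSG (variant 1) k-nearest-neighbour mutual information, in nats.

    MI = ψ(k) + ψ(n) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩ where n_x, n_y count the
    marginal neighbours strictly inside the Chebyshev distance to the k-th
    joint neighbour. Small negative estimates are clipped to 0 with the
    ``clipped`` flag set. Heavily tied inputs (ties in either marginal at
    more than half the points) set ``tie_warning`` — the estimator assumes
    continuous marginals.

    Returns (mi_nats, clipped, tie_warning).
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if k < 1 or n <= k + 1:
        raise ValueError("need k >= 1 and n > k + 1")

    tie_warning = bool(
        (n - np.unique(x).size) > n / 2 or (n - np.unique(y).size) > n / 2
    )

    dx = np.abs(x[:, None] - x[None, :])
    dy = np.abs(y[:, None] - y[None, :])
    dz = np.maximum(dx, dy)
    np.fill_diagonal(dz, np.inf)
    # Chebyshev distance to the k-th neighbour in the joint space.
    eps = np.partition(dz, k - 1, axis=1)[:, k - 1]
    np.fill_diagonal(dx, np.inf)
    np.fill_diagonal(dy, np.inf)
    nx = (dx < eps[:, None]).sum(axis=1)
    ny = (dy < eps[:, None]).sum(axis=1)
    mi = digamma(k) + digamma(n) - float(np.mean(digamma(nx + 1) + digamma(ny + 1)))
    clipped = mi < 0
    return (0.0 if clipped else float(mi)), bool(clipped), tie_warning


@dataclass
class CovariationTable:
    """Per-pair results plus distribution summaries of Spearman rho."""

    results: list[CovariationResult]
    mean_spearman: float | None
    median_spearman: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "reaction_id": r.reaction_id,
                    "protein_id": r.protein_id,
                    "n": r.n_conditions,
                    "spearman": r.spearman_rho,
                    "pearson_linear": r.pearson_r_linear,
                    "pearson_log2": r.pearson_r_log,
                    "mi_nats": r.mutual_information,
                    "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "reaction_id", "protein_id", "n", "spearman",
                "pearson_linear", "pearson_log2", "mi_nats", "flags",
            ],
        )


def covariation_table(pairs: list[FocalPair], k: int = 3) -> CovariationTable:
    """All covariation statistics for each focal pair, plus summaries.

    Spearman is computed from raw abundances; by rank invariance this equals
    the log-abundance Spearman. Pairs whose condition series is empty after
    exclusions never reach here (extract_focal_pairs drops them).
    """
    if not pairs:
        raise ValueError("no focal pairs to summarize")
    results: list[CovariationResult] = []
    for pair in pairs:
        flags: list[str] = []
        rho, zv = spearman(pair.abundances, pair.rates)
        r_lin, zv_lin = pearson(pair.abundances, pair.rates, log_transform_x=False)
        r_log, _ = pearson(pair.abundances, pair.rates, log_transform_x=True)
        zero_var = zv or zv_lin
        if zero_var:
            flags.append("ZERO_VARIANCE")
        n = len(pair.condition_ids)
        mi = clipped = tie = None
        if not zero_var and n > k + 1:
            mi, clipped, tie = mutual_information(pair.abundances, pair.rates, k=k)
            if clipped:
                flags.append("MI_CLIPPED")
            if tie:
                flags.append("MI_TIES")
        results.append(
            CovariationResult(
                reaction_id=pair.reaction_id,
                protein_id=pair.protein_id,
                n_conditions=n,
                spearman_rho=rho,
                pearson_r_linear=r_lin,
                pearson_r_log=r_log,
                mutual_information=mi,
                zero_variance_flag=zero_var,
                mi_clipped=bool(clipped),
                mi_tie_warning=bool(tie),
                flags=flags,
            )
        )
    rhos = np.array([r.spearman_rho for r in results if r.spearman_rho is not None])
    mean = float(rhos.mean()) if rhos.size else None
    median = float(np.median(rhos)) if rhos.size else None
    return CovariationTable(results=results, mean_spearman=mean, median_spearman=median)
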