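"""Branched-pathway toy model with first-order enzyme kinetics.

Two enzymes compete for a single shared substrate S1 that is supplied at a
constant rate C. With first-order kinetics v = k·e·s, the steady state of

    C ->  S1  --(k1, e1)-->  v1
           \\--(k2, e2)-->  v2

is closed-form: S1 = C / (k1·e1 + k2·e2), so v1 + v2 = C exactly. When e2 is
co-regulated with e1 (e.g. e2 grows faster than e1), raising the focal
enzyme e1 can *lower* its own reaction rate v1 — the motif that breaks the
naive "more enzyme, more flux" reading of expression data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

__all__ = ["ToyBranchedPathway", "toy_steady_state", "toy_covariation_sweep"]


@dataclass(frozen=True)
class ToyBranchedPathway:
    """Parameters of the branched motif.

    k1, k2 — first-order rate constants (per time per substrate unit, ≥ 0;
    at least one branch must drain substrate). C — substrate supply rate
    (> 0). e1, e2 — enzyme concentrations (≥ 0).
    """

    k1: float
    k2: float
    C: float
    e1: float
    e2: float

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.e1, self.e2) < 0 or self.C <= 0:
            raise ValueError("rate constants/enzymes must be >= 0 and supply C > 0")
        if self.k1 * self.e1 + self.k2 * self.e2 <= 0:
            raise ValueError("no active branch: k1*e1 + k2*e2 must be > 0")


def toy_steady_state(p: ToyBranchedPathway) -> tuple[float, float, float]:
    """Steady-state (S1, v1, v2) of the branched motif.

    S1 = C/(k1·e1 + k2·e2); v_i = k_i·e_i·S1. Mass balance v1 + v2 = C holds
    identically.
    """
    drain = p.k1 * p.e1 + p.k2 * p.e2
    s1 = p.C / drain
    return s1, p.k1 * p.e1 * s1, p.k2 * p.e2 * s1


def toy_covariation_sweep(
    p_base: ToyBranchedPathway,
    e1_grid: Iterable[float],
    coupling: Callable[[float], float],
) -> tuple[pd.DataFrame, float | None, bool]:
    """Sweep e1 over a grid with e2 = coupling(e1); correlate e1 with v1.

    Returns (table of e1/e2/v1 rows, Spearman rho, zero_variance_flag). When
    v1 is flat across the grid — e.g. proportional coupling e2 ∝ e1 makes
    v1 = C·k1·e1/(k1·e1 + k2·c·e1) constant — the correlation is undefined
    and reported as None with the flag set.
    """
    grid = [float(v) for v in e1_grid]
    if len(set(grid)) < 3:
        raise ValueError("e1 grid must contain at least 3 distinct values")
    rows = []
    for e1 in grid:
        e2 = float(coupling(e1))
        _, v1, _ = toy_steady_state(
            ToyBranchedPathway(p_base.k1, p_base.k2, p_base.C, e1, e2)
        )
        rows.append((e1, e2, v1))
    table = pd.DataFrame(rows, columns=["e1", "e2", "v1"])
    from .covariation import spearman  # local import: covariation owns the statistic

    rho, flag = spearman(table["e1"].to_numpy(), table["v1"].to_numpy())
    return table, rho, flag
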