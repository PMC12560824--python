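"""Ground-truth chemostat-style dataset generator.

Emulates the structure of steady-state continuous-culture proteomics/flux
studies: a factorial design of M limiting media × D dilution rates, proteins
whose log₂ abundances respond to the latent condition factors (growth rate
and media identity) with log-normal marginals, and reaction rates that are
deterministic closed-form functions of the realized (noisy) enzyme
abundances and substrate supply. Three reaction archetypes span the range of
focal-enzyme covariation:

* ``simple_constant`` — v = k·e with fixed substrate absorbed into k: the
  focal enzyme alone determines the rate (strong positive covariation).
* ``simple_hidden``  — v = k·e·S_media with a media-specific substrate
  supply the proteome does not directly report (weakened covariation).
* ``branched``       — the two-enzyme competition motif: v1 from the
  branched-pathway steady state with the competitor's media response
  amplified by ``coupling_slope``, so the focal enzyme can anti-correlate
  with its own rate.

Bystander proteins carry condition information but no reaction. Every motif
plus a draw of bystanders forms a pathway subsystem (bystanders may sit in
several subsystems, as real pathway annotations overlap). A ``truth``
side-channel records every latent draw so tests can re-derive the rates
independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AnnotationMap,
    ConditionDesign,
    ExpressionMatrix,
    RateTable,
    read_annotations,
    read_conditions,
    read_matrix,
    write_annotations,
    write_conditions,
    write_matrix,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_dataset",
    "evaluate_truth_rates",
    "write_dataset",
    "read_dataset",
]

_MEDIA_NAMES = ["glucose", "ammonium", "phosphate", "leucine", "uracil"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs; defaults are the benchmark conditions.

    5 media × 5 dilution rates (25 chemostats), 200 proteins of which 150
    are bystanders, 40 reactions (10 simple-constant, 20 simple-hidden,
    10 branched), expression noise 0.25 log₂ units.
    """

    n_media: int = 5
    n_growth_rates: int = 5
    growth_rate_values: tuple[float, ...] | None = None  # default: 0.05..0.30 h⁻¹
    n_bystander_proteins: int = 150
    n_simple_constant: int = 10
    n_simple_hidden: int = 20
    n_branched: int = 10
    noise_sd_log2: float = 0.25
    coupling_slope: float = 2.0
    hidden_substrate_sd_log2: float = 2.5
    bystanders_per_subsystem: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_media, self.n_growth_rates, self.n_bystander_proteins,
            self.n_simple_constant, self.n_simple_hidden, self.n_branched,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.growth_rate_values is not None:
            g = tuple(float(v) for v in self.growth_rate_values)
            if len(g) != self.n_growth_rates or any(v <= 0 for v in g):
                raise ValueError("growth_rate_values must be n_growth_rates positive reals")
            object.__setattr__(self, "growth_rate_values", g)

    @property
    def n_reactions(self) -> int:
        return self.n_simple_constant + self.n_simple_hidden + self.n_branched

    def growth_grid(self) -> np.ndarray:
        if self.growth_rate_values is not None:
            return np.array(self.growth_rate_values)
        return np.linspace(0.05, 0.30, self.n_growth_rates)

    def media_labels(self) -> list[str]:
        return [
            _MEDIA_NAMES[i] if i < len(_MEDIA_NAMES) else f"media_{i + 1}"
            for i in range(self.n_media)
        ]


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    rates: RateTable
    design: ConditionDesign
    annotations: AnnotationMap
    truth: dict = field(repr=False)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Draw one complete synthetic dataset.

    Per protein i and condition c: log₂ e_{i,c} = b_i + s_i·g_c +
    m_{i,media(c)} + ε with b ~ N(0,1), s ~ N(0,0.5), m ~ N(0,0.5),
    ε ~ N(0, noise_sd_log2²). Substrate supply for branched motifs grows
    with dilution rate, C_c = C₀·(1+g_c). All draws come from substreams of
    the single config seed, so regeneration is bit-identical.
    """
    if cfg.n_media * cfg.n_growth_rates == 0:
        raise ValueError("the design has zero conditions")
    if cfg.n_reactions == 0:
        raise ValueError("the design has zero reactions")

    media = cfg.media_labels()
    growth = cfg.growth_grid()
    cond_rows = []
    for m in media:
        for j, g in enumerate(growth, start=1):
            cond_rows.append((f"{m}_D{j}", m, float(g)))
    cond_ids = [r[0] for r in cond_rows]
    design = ConditionDesign(
        pd.DataFrame(
            {"media_type": [r[1] for r in cond_rows], "growth_rate": [r[2] for r in cond_rows]},
            index=pd.Index(cond_ids, name="condition_id"),
        )
    )
    cond_media = np.array([r[1] for r in cond_rows])
    cond_growth = np.array([r[2] for r in cond_rows])

    # --- protein roster ----------------------------------------------------
    width = max(2, len(str(max(cfg.n_reactions, cfg.n_bystander_proteins, 1))))

    def _ids(prefix: str, n: int) -> list[str]:
        return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]

    sc_reactions = _ids("R_SC", cfg.n_simple_constant)
    sh_reactions = _ids("R_SH", cfg.n_simple_hidden)
    br_reactions = _ids("R_BR", cfg.n_branched)
    sc_prot = [r.replace("R_", "P_") for r in sc_reactions]
    sh_prot = [r.replace("R_", "P_") for r in sh_reactions]
    br_focal = [r.replace("R_", "P_") + "F" for r in br_reactions]
    br_comp = [r.replace("R_", "P_") + "C" for r in br_reactions]
    bystanders = _ids("P_BY", cfg.n_bystander_proteins)
    proteins = sc_prot + sh_prot + br_focal + br_comp + bystanders

    # --- latent protein parameters ----------------------------------------
    rng_prot = _rng(cfg.seed, 0)
    n_prot = len(proteins)
    baseline = rng_prot.normal(0.0, 1.0, n_prot)
    slope = rng_prot.normal(0.0, 0.5, n_prot)
    media_eff = rng_prot.normal(0.0, 0.5, (n_prot, cfg.n_media))
    pidx = {p: i for i, p in enumerate(proteins)}
    # competitor enzymes track their focal partner's media response, amplified
    for f, c in zip(br_focal, br_comp):
        media_eff[pidx[c]] = cfg.coupling_slope * media_eff[pidx[f]]

    # --- expression --------------------------------------------------------
    rng_noise = _rng(cfg.seed, 1)
    midx = {m: i for i, m in enumerate(media)}
    cond_midx = np.array([midx[m] for m in cond_media])
    log2e = (
        baseline[:, None]
        + slope[:, None] * cond_growth[None, :]
        + media_eff[:, cond_midx]
        + rng_noise.normal(0.0, cfg.noise_sd_log2, (n_prot, len(cond_ids)))
    )
    expr_df = pd.DataFrame(
        np.exp2(log2e), index=pd.Index(proteins, name="protein_id"), columns=cond_ids
    )
    expression = ExpressionMatrix(expr_df)

    # --- reaction kinetics -------------------------------------------------
    rng_kin = _rng(cfg.seed, 2)
    reactions: dict[str, dict] = {}
    for rid, pid in zip(sc_reactions, sc_prot):
        reactions[rid] = {
            "type": "simple_constant",
            "focal_protein": pid,
            "k": float(np.exp2(rng_kin.uniform(-1, 1))),
        }
    for rid, pid in zip(sh_reactions, sh_prot):
        reactions[rid] = {
            "type": "simple_hidden",
            "focal_protein": pid,
            "k": float(np.exp2(rng_kin.uniform(-1, 1))),
            "substrate_by_media": {
                m: float(np.exp2(rng_kin.normal(0.0, cfg.hidden_substrate_sd_log2)))
                for m in media
            },
        }
    for rid, f, c in zip(br_reactions, br_focal, br_comp):
        reactions[rid] = {
            "type": "branched",
            "focal_protein": f,
            "competitor_protein": c,
            "k1": float(np.exp2(rng_kin.uniform(-1, 1))),
            "k2": float(np.exp2(rng_kin.uniform(-1, 1))),
            "C0": float(np.exp2(rng_kin.uniform(0, 2))),
        }

    truth = {
        "schema_version": 1,
        "config": asdict(cfg),
        "condition_factors": {
            cid: {"media": m, "growth_rate": float(g)}
            for cid, m, g in zip(cond_ids, cond_media, cond_growth)
        },
        "protein_params": {
            p: {
                "baseline": float(baseline[i]),
                "growth_slope": float(slope[i]),
                "media_effects": {m: float(media_eff[i, midx[m]]) for m in media},
            }
            for p, i in pidx.items()
        },
        "reactions": reactions,
    }

    rate_df = evaluate_truth_rates(truth, expr_df, design)
    rates = RateTable(rate_df)

    # --- annotations: one subsystem per motif ------------------------------
    rng_sub = _rng(cfg.seed, 3)
    r2p: dict[str, frozenset[str]] = {}
    p2s: dict[str, set[str]] = {}
    r2s: dict[str, str] = {}
    for rid, spec_ in reactions.items():
        members = [spec_["focal_protein"]]
        if spec_["type"] == "branched":
            members.append(spec_["competitor_protein"])
        r2p[rid] = frozenset([spec_["focal_protein"]])
        sub = f"subsystem_{rid[2:]}"
        r2s[rid] = sub
        n_by = min(cfg.bystanders_per_subsystem, cfg.n_bystander_proteins)
        if n_by:
            members += list(rng_sub.choice(bystanders, size=n_by, replace=False))
        for p in members:
            p2s.setdefault(p, set()).add(sub)
    annotations = AnnotationMap(
        reaction_to_proteins=r2p,
        protein_to_subsystems={p: frozenset(s) for p, s in p2s.items()},
        reaction_to_subsystem=r2s,
    )

    return SyntheticDataset(expression, rates, design, annotations, truth)


def evaluate_truth_rates(
    truth: dict, expression: pd.DataFrame, design: ConditionDesign
) -> pd.DataFrame:
    """Re-evaluate every reaction's closed-form rate on given abundances.

    This is the generative law itself: rates are deterministic functions of
    the realized expression values and the latent condition factors, so the
    returned table reproduces the dataset's rates exactly — and serves as an
    independent oracle when called on the written-out files.
    """
    cond_ids = list(expression.columns)
    media = np.array([truth["condition_factors"][c]["media"] for c in cond_ids])
    growth = np.array([truth["condition_factors"][c]["growth_rate"] for c in cond_ids])
    rows = {}
    for rid, spec_ in truth["reactions"].items():
        e = expression.loc[spec_["focal_protein"]].to_numpy()
        if spec_["type"] == "simple_constant":
            rows[rid] = spec_["k"] * e
        elif spec_["type"] == "simple_hidden":
            s = np.array([spec_["substrate_by_media"][m] for m in media])
            rows[rid] = spec_["k"] * e * s
        elif spec_["type"] == "branched":
            e2 = expression.loc[spec_["competitor_protein"]].to_numpy()
            c_supply = spec_["C0"] * (1.0 + growth)
            s1 = c_supply / (spec_["k1"] * e + spec_["k2"] * e2)
            rows[rid] = spec_["k1"] * e * s1
        else:  # pragma: no cover - schema guard
            raise ValueError(f"unknown reaction type {spec_['type']!r}")
    return pd.DataFrame(rows, index=cond_ids).T.rename_axis("reaction_id")


def write_dataset(d: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the dataset in the pipeline's on-disk formats plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(d.expression, out / "expression.tsv")
    write_matrix(d.rates, out / "rates.tsv")
    write_conditions(d.design, out / "conditions.tsv")
    write_annotations(
        d.annotations,
        out / "reaction_protein.tsv",
        out / "subsystems.gmt",
        out / "reaction_subsystem.tsv",
    )
    (out / "truth.json").write_text(json.dumps(d.truth, indent=1))


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read back a directory written by :func:`write_dataset`."""
    p = Path(in_dir)
    return SyntheticDataset(
        expression=read_matrix(p / "expression.tsv", "expression"),
        rates=read_matrix(p / "rates.tsv", "rate"),
        design=read_conditions(p / "conditions.tsv"),
        annotations=read_annotations(
            p / "reaction_protein.tsv", p / "subsystems.gmt", p / "reaction_subsystem.tsv"
        ),
        truth=json.loads((p / "truth.json").read_text()),
    )
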