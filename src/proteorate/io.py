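"""Core data containers and on-disk formats.

Four containers describe a steady-state culture experiment:

* :class:`ExpressionMatrix` — protein abundances (strictly positive, linear
  scale) per condition.
* :class:`RateTable` — metabolic reaction rates per condition (zeros and
  negative values allowed; rates are signed fluxes).
* :class:`ConditionDesign` — the factorial design behind the conditions:
  which limiting medium, which dilution (growth) rate.
* :class:`AnnotationMap` — how reactions, proteins and pathway subsystems
  relate.

All tabular files are plain TSV (tab separator, ``.`` decimal, UTF-8, header
row mandatory, no quoting). Subsystem membership uses the GMT gene-set
format. The containers enforce a complete-case contract: missing cells are a
hard error, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RateTable",
    "ConditionDesign",
    "AnnotationMap",
    "MatrixFormatError",
    "ValidationError",
    "read_matrix",
    "write_matrix",
    "read_conditions",
    "write_conditions",
    "read_annotations",
    "write_annotations",
    "log2_transform",
    "zscore_by_protein",
]


class MatrixFormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


class ValidationError(ValueError):
    """Raised when containers are mutually inconsistent."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    dupes = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dupes:
        raise MatrixFormatError(f"duplicate {what}: {sorted(set(dupes))}")
    return ids


@dataclass
class _LabelledMatrix:
    """Shared behaviour of expression and rate tables.

    ``data`` is a DataFrame with row ids on the index and condition ids as
    columns; construction validates completeness and uniqueness.
    """

    data: pd.DataFrame

    _row_kind: str = field(default="row_id", init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, self._row_kind)
        _check_unique(df.columns, "condition_id")
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise MatrixFormatError(f"non-numeric columns: {bad}")
        if df.isna().any().any():
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise MatrixFormatError(
                f"missing value at ({df.index[r]}, {df.columns[c]}); "
                "complete-case input is required"
            )
        self.data = df.astype(float)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __eq__(self, other: object) -> bool:
        return type(other) is type(self) and self.data.equals(other.data)  # type: ignore[attr-defined]


@dataclass(eq=False)
class ExpressionMatrix(_LabelledMatrix):
    """Proteins × conditions abundance matrix, strictly positive linear scale.

    ``units`` is free-text metadata (relative or molar units); it does not
    affect any computation because every downstream statistic is either
    scale-free or applied after a log transform.
    """

    units: str = "relative"

    def __post_init__(self) -> None:
        self._row_kind = "protein_id"
        super().__post_init__()
        vals = self.data.to_numpy()
        if not (vals > 0).all():
            r, c = np.argwhere(~(vals > 0))[0]
            raise MatrixFormatError(
                f"non-positive abundance {vals[r, c]!r} at "
                f"({self.data.index[r]}, {self.data.columns[c]}); "
                "expression values must be > 0 for the log2 transform"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(eq=False)
class RateTable(_LabelledMatrix):
    """Reactions × conditions rate matrix; zero and negative rates are legal."""

    units: str = "umol/h/mL cell volume"

    def __post_init__(self) -> None:
        self._row_kind = "reaction_id"
        super().__post_init__()

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class ConditionDesign:
    """Condition metadata: limiting-medium label and dilution/growth rate.

    The chemostat design is factorial: each condition is one medium grown at
    one dilution rate (h⁻¹), and (media_type, growth_rate) pairs are unique.
    """

    table: pd.DataFrame  # index: condition_id; columns: media_type, growth_rate

    def __post_init__(self) -> None:
        t = self.table
        missing = {"media_type", "growth_rate"} - set(t.columns)
        if missing:
            raise MatrixFormatError(f"condition table lacks columns: {sorted(missing)}")
        _check_unique(t.index, "condition_id")
        if (t["growth_rate"].astype(float) < 0).any():
            raise MatrixFormatError("growth_rate must be non-negative")
        pairs = list(zip(t["media_type"], t["growth_rate"].astype(float)))
        if len(set(pairs)) != len(pairs):
            raise MatrixFormatError("(media_type, growth_rate) pairs must be unique")
        self.table = t.assign(growth_rate=t["growth_rate"].astype(float))

    @property
    def condition_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def media_types(self) -> list[str]:
        return list(dict.fromkeys(self.table["media_type"]))

    @property
    def growth_rates(self) -> np.ndarray:
        return self.table["growth_rate"].to_numpy()

    def validate_against(self, *matrices: _LabelledMatrix) -> None:
        """Every condition of every matrix must appear exactly once here."""
        known = set(self.condition_ids)
        for m in matrices:
            unknown = [c for c in m.condition_ids if c not in known]
            if unknown:
                raise ValidationError(f"conditions missing from design: {unknown}")


@dataclass
class AnnotationMap:
    """Reaction↔protein and protein/reaction↔subsystem relations.

    A reaction may map to zero or many proteins; restricting to reactions
    with a single catalysing protein (the focal-enzyme filter) happens
    downstream, not here.
    """

    reaction_to_proteins: dict[str, frozenset[str]]
    protein_to_subsystems: dict[str, frozenset[str]]
    reaction_to_subsystem: dict[str, str]

    def subsystem_members(self, subsystem: str) -> frozenset[str]:
        return frozenset(
            p for p, subs in self.protein_to_subsystems.items() if subsystem in subs
        )

    @property
    def subsystems(self) -> list[str]:
        out: dict[str, None] = {}
        for subs in self.protein_to_subsystems.values():
            for s in sorted(subs):
                out.setdefault(s)
        return list(out)

    def validate_against(self, rates: RateTable, expr: ExpressionMatrix) -> None:
        """Relations may only reference reactions/proteins the matrices know."""
        known_r = set(rates.reaction_ids)
        known_p = set(expr.protein_ids)
        bad_r = sorted(
            set(self.reaction_to_proteins) - known_r
            | set(self.reaction_to_subsystem) - known_r
        )
        bad_p = sorted(
            {p for ps in self.reaction_to_proteins.values() for p in ps} - known_p
            | set(self.protein_to_subsystems) - known_p
        )
        if bad_r or bad_p:
            msgs = []
            if bad_r:
                msgs.append(f"unknown reactions: {bad_r}")
            if bad_p:
                msgs.append(f"unknown proteins: {bad_p}")
            raise ValidationError("; ".join(msgs))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_HEADER = {"expression": "protein_id", "rate": "reaction_id"}


def read_matrix(path: str | Path, kind: str) -> ExpressionMatrix | RateTable:
    """Read an expression or rate TSV.

    The first header cell must be ``protein_id`` (kind="expression") or
    ``reaction_id`` (kind="rate"); the remaining header cells are condition
    ids. Errors name the offending cell by row/column label.
    """
    if kind not in _HEADER:
        raise ValueError(f"kind must be 'expression' or 'rate', got {kind!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != _HEADER[kind]:
        raise MatrixFormatError(
            f"{path}: first header cell must be {_HEADER[kind]!r}, got {df.columns[0]!r}"
        )
    df = df.set_index(df.columns[0])
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                if raw == "":
                    raise ValueError("empty cell")
                v = float(raw)
                if not math.isfinite(v):
                    raise ValueError("non-finite")
            except ValueError as exc:
                raise MatrixFormatError(
                    f"{path}: cell ({df.index[i]}, {col}) = {raw!r}: {exc}"
                ) from None
            parsed.iloc[i, j] = v
    cls = ExpressionMatrix if kind == "expression" else RateTable
    return cls(parsed)


def write_matrix(m: ExpressionMatrix | RateTable, path: str | Path) -> None:
    """Write a matrix TSV; float formatting round-trips values exactly."""
    header = _HEADER["expression" if isinstance(m, ExpressionMatrix) else "rate"]
    df = m.data.copy()
    df.index.name = header
    # repr() of a Python float is the shortest exact decimal; read_matrix
    # recovers the identical binary value.
    df.map(lambda v: repr(float(v))).to_csv(path, sep="\t")


def read_conditions(path: str | Path) -> ConditionDesign:
    """Read 3-column condition metadata (condition_id, media_type, growth_rate)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["condition_id", "media_type", "growth_rate"]
    if list(df.columns) != expected:
        raise MatrixFormatError(f"{path}: header must be {expected}, got {list(df.columns)}")
    try:
        rates = df["growth_rate"].astype(float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric growth_rate: {exc}") from None
    table = pd.DataFrame(
        {"media_type": df["media_type"].to_numpy(), "growth_rate": rates.to_numpy()},
        index=pd.Index(df["condition_id"], name="condition_id"),
    )
    return ConditionDesign(table)


def write_conditions(design: ConditionDesign, path: str | Path) -> None:
    t = design.table.copy()
    t["growth_rate"] = t["growth_rate"].map(lambda v: repr(float(v)))
    t.to_csv(path, sep="\t")


def _read_two_col(path: Path, cols: tuple[str, str]) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise MatrixFormatError(f"{path}: expected 2 columns, got {len(header)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            rows.append((parts[0], parts[1]))
    return rows


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT file: set name, description, tab-separated member ids."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise MatrixFormatError(f"{path}:{lineno}: GMT line needs name and description")
            name = parts[0]
            if not name:
                raise MatrixFormatError(f"{path}:{lineno}: empty set name")
            sets[name] = frozenset(p for p in parts[2:] if p)
    return sets


def read_annotations(
    mapping_path: str | Path,
    gmt_path: str | Path,
    reaction_subsystem_path: str | Path,
) -> AnnotationMap:
    """Assemble an AnnotationMap from its three on-disk pieces.

    Duplicate (reaction, protein) pairs are deduplicated silently; empty sets
    are allowed. Referential checks against the matrices happen in
    :meth:`AnnotationMap.validate_against`.
    """
    r2p: dict[str, set[str]] = {}
    for rid, pid in _read_two_col(Path(mapping_path), ("reaction_id", "protein_id")):
        r2p.setdefault(rid, set()).add(pid)
    subsystem_sets = read_gmt(gmt_path)
    p2s: dict[str, set[str]] = {}
    for name, members in subsystem_sets.items():
        for p in members:
            p2s.setdefault(p, set()).add(name)
    r2s = dict(_read_two_col(Path(reaction_subsystem_path), ("reaction_id", "subsystem")))
    return AnnotationMap(
        reaction_to_proteins={r: frozenset(v) for r, v in r2p.items()},
        protein_to_subsystems={p: frozenset(v) for p, v in p2s.items()},
        reaction_to_subsystem=r2s,
    )


def write_annotations(ann: AnnotationMap, mapping_path, gmt_path, reaction_subsystem_path) -> None:
    with open(mapping_path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tprotein_id\n")
        for rid in sorted(ann.reaction_to_proteins):
            for pid in sorted(ann.reaction_to_proteins[rid]):
                fh.write(f"{rid}\t{pid}\n")
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for name in ann.subsystems:
            members = "\t".join(sorted(ann.subsystem_members(name)))
            fh.write(f"{name}\tsynthetic subsystem\t{members}\n")
    with open(reaction_subsystem_path, "w", encoding="utf-8") as fh:
        fh.write("reaction_id\tsubsystem\n")
        for rid in sorted(ann.reaction_to_subsystem):
            fh.write(f"{rid}\t{ann.reaction_to_subsystem[rid]}\n")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def log2_transform(m: ExpressionMatrix) -> pd.DataFrame:
    """log₂ of every abundance; defined everywhere because values are > 0."""
    return np.log2(m.data)


def zscore_by_protein(transformed: pd.DataFrame) -> pd.DataFrame:
    """Z-score each protein row across conditions (sample sd, n−1 denominator).

    Constant rows make the z-score undefined and raise, naming the protein.
    """
    if transformed.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 conditions")
    sd = transformed.std(axis=1, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"constant abundance row(s), z-score undefined: {list(flat.index)}")
    return transformed.sub(transformed.mean(axis=1), axis=0).div(sd, axis=0)
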