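"""Domain types shared by every other module.

A cohort is a samples-by-variables table with per-entry missingness, a binary
outcome, and an ordered partition of the variables into named modality blocks.
Missingness is expected to be *modular*: a sample either has a whole block of
variables or lacks the whole examination. This module owns variable encoding
(0/1 indicators, one-hot, optional train-fitted standardization), the
stage-eligibility rule, and class-balance oversampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VARIABLE_KINDS = ("binary", "categorical", "continuous")

__all__ = [
    "VariableSpec",
    "ModalityPartition",
    "CohortTable",
    "DesignMatrix",
    "Encoder",
    "aggregate_repeats",
    "encode",
    "stage_eligible",
    "block_presence",
    "oversample",
    "oversample_indices",
    "ProfuseError",
    "SingleClassError",
    "RepeatValueError",
]


class ProfuseError(Exception):
    """Base class for typed errors raised by this package."""


class SingleClassError(ProfuseError):
    """Raised when an operation requires both outcome classes."""


class RepeatValueError(ProfuseError):
    """Raised when repeated measurements cannot be aggregated."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one cohort variable.

    ``binary`` values encode to a single 0/1 column, ``categorical`` to one
    indicator column per category, ``continuous`` passes through (optionally
    standardized with training-set statistics).
    """

    name: str
    kind: str
    categories: tuple[str, ...] | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "categorical":
            if self.categories is not None and len(set(self.categories)) < 2:
                raise ValueError(
                    f"categorical variable {self.name!r} needs >=2 distinct categories"
                )
        if self.categories is not None:
            object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))


@dataclass(frozen=True)
class ModalityPartition:
    """Ordered assignment of every variable to exactly one named block.

    The block order defines the fusion chain x(1), ..., x(T); ``fixed_prefix``
    blocks are pinned at the front and excluded from order search.
    """

    blocks: tuple[tuple[str, tuple[str, ...]], ...]
    fixed_prefix: int = 1

    def __post_init__(self) -> None:
        blocks = tuple((str(n), tuple(v)) for n, v in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        names = [n for n, _ in blocks]
        if len(set(names)) != len(names):
            raise ValueError("block names must be unique")
        all_vars = [v for _, vs in blocks for v in vs]
        if len(set(all_vars)) != len(all_vars):
            raise ValueError("each variable may appear in exactly one block")
        if not 1 <= self.fixed_prefix <= len(blocks):
            raise ValueError(
                f"fixed_prefix must be in [1, {len(blocks)}], got {self.fixed_prefix}"
            )

    @property
    def T(self) -> int:
        return len(self.blocks)

    @property
    def block_names(self) -> list[str]:
        return [n for n, _ in self.blocks]

    def block_variables(self, name_or_index: str | int) -> tuple[str, ...]:
        if isinstance(name_or_index, int):
            return self.blocks[name_or_index][1]
        for n, vs in self.blocks:
            if n == name_or_index:
                return vs
        raise KeyError(name_or_index)

    def variables_upto(self, t: int) -> list[str]:
        """All variable names of blocks 1..t (1-based)."""
        if not 1 <= t <= self.T:
            raise ValueError(f"stage index t must be in [1, {self.T}], got {t}")
        return [v for _, vs in self.blocks[:t] for v in vs]

    @property
    def variable_names(self) -> list[str]:
        return self.variables_upto(self.T)

    def prefix(self, t: int) -> "ModalityPartition":
        """Partition restricted to the first t blocks."""
        if not 1 <= t <= self.T:
            raise ValueError(f"t must be in [1, {self.T}], got {t}")
        return ModalityPartition(self.blocks[:t], fixed_prefix=min(self.fixed_prefix, t))

    def drop_block(self, name: str) -> "ModalityPartition":
        """Partition with one block removed; surviving order intact."""
        if name not in self.block_names:
            raise KeyError(name)
        kept = tuple(b for b in self.blocks if b[0] != name)
        if not kept:
            raise ValueError("removal would leave zero blocks")
        return ModalityPartition(kept, fixed_prefix=min(self.fixed_prefix, len(kept)))

    def reorder(self, names: list[str]) -> "ModalityPartition":
        if sorted(names) != sorted(self.block_names):
            raise ValueError("reorder must use exactly the existing block names")
        lookup = dict(self.blocks)
        return ModalityPartition(
            tuple((n, lookup[n]) for n in names), fixed_prefix=self.fixed_prefix
        )

    # -- config round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "blocks": {n: list(vs) for n, vs in self.blocks},
            "fixed_prefix": self.fixed_prefix,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModalityPartition":
        blocks = tuple((n, tuple(vs)) for n, vs in d["blocks"].items())
        return cls(blocks, fixed_prefix=int(d.get("fixed_prefix", 1)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModalityPartition":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortTable:
    """Samples x variables grid with missing entries and a binary outcome.

    ``values`` is a DataFrame indexed by sample id; continuous/binary cells are
    floats, categorical cells are category labels, missing cells are NaN.
    ``repeated_measurements`` optionally holds per-(sample, variable) lists of
    raw values prior to aggregation.
    """

    values: pd.DataFrame
    outcome: pd.Series
    variables: list[VariableSpec] = field(default_factory=list)
    repeated_measurements: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("variable names must be unique")
        if not self.variables:
            self.variables = [_infer_spec(self.values[c]) for c in self.values.columns]
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        if list(self.values.columns) != names:
            raise ValueError("values columns must match variable specs")
        self.outcome = self.outcome.reindex(self.values.index)
        if self.outcome.isna().any():
            raise ValueError("outcome must never be missing")
        out = set(pd.unique(self.outcome))
        if not out <= {0, 1}:
            raise ValueError(f"outcome labels must be in {{0,1}}, got {sorted(out)}")
        self.outcome = self.outcome.astype(int)

    # -- convenience ---------------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def missing_mask(self) -> pd.DataFrame:
        """True where the cell is missing."""
        return self.values.isna()

    def subset(self, sample_ids) -> "CohortTable":
        return CohortTable(
            values=self.values.loc[sample_ids].copy(),
            outcome=self.outcome.loc[sample_ids].copy(),
            variables=list(self.variables),
        )

    def select_variables(self, names: list[str]) -> "CohortTable":
        specs = [self.spec(n) for n in names]
        return CohortTable(
            values=self.values[names].copy(),
            outcome=self.outcome.copy(),
            variables=specs,
        )

    # -- CSV round-trip ------------------------------------------------------

    def to_csv(self, path, outcome_column: str = "outcome") -> None:
        frame = self.values.copy()
        frame[outcome_column] = self.outcome
        frame.to_csv(path, index_label="sample_id", na_rep="NA")

    @classmethod
    def from_csv(
        cls,
        path,
        outcome_column: str = "outcome",
        variables: list[VariableSpec] | None = None,
        repeats_path=None,
    ) -> "CohortTable":
        frame = pd.read_csv(path, index_col="sample_id", na_values=["NA", ""], comment="#")
        frame.index = frame.index.astype(str)
        outcome = frame.pop(outcome_column)
        if variables is not None:
            frame = frame[[v.name for v in variables]]
            for v in variables:
                if v.kind == "categorical":
                    frame[v.name] = frame[v.name].astype(object)
                    mask = frame[v.name].notna()
                    frame.loc[mask, v.name] = frame.loc[mask, v.name].astype(str)
        repeats: dict[tuple[str, str], list[float]] = {}
        if repeats_path is not None:
            long = pd.read_csv(repeats_path, dtype={"sample_id": str, "variable": str})
            for (sid, var), grp in long.groupby(["sample_id", "variable"]):
                repeats[(sid, var)] = list(grp["value"])
        return cls(values=frame, outcome=outcome, variables=variables or [],
                   repeated_measurements=repeats)


def _infer_spec(col: pd.Series) -> VariableSpec:
    """Fallback spec inference used when a table is built without declarations."""
    non_missing = col.dropna()
    if non_missing.dtype == object:
        cats = tuple(sorted(set(non_missing.astype(str))))
        return VariableSpec(str(col.name), "categorical", categories=cats)
    uniq = set(np.unique(non_missing.to_numpy(dtype=float))) if len(non_missing) else set()
    if uniq <= {0.0, 1.0} and len(uniq) > 0:
        return VariableSpec(str(col.name), "binary")
    return VariableSpec(str(col.name), "continuous")


# ---------------------------------------------------------------------------
# repeated-measurement aggregation
# ---------------------------------------------------------------------------


def aggregate_repeats(table: CohortTable) -> CohortTable:
    """Collapse repeated measurements of one (sample, variable) to their median.

    Entries without repeats are left untouched; the operation is idempotent
    because the aggregated table carries no repeat lists.
    """
    values = table.values.copy()
    for (sid, var), raw in table.repeated_measurements.items():
        spec = table.spec(var)
        try:
            arr = np.asarray(raw, dtype=float)
        except (TypeError, ValueError) as err:
            raise RepeatValueError(
                f"non-numeric repeated values for variable {var!r}, sample {sid!r}"
            ) from err
        if arr.size == 0:
            continue
        values.loc[sid, var] = float(np.median(arr))
    return CohortTable(values=values, outcome=table.outcome.copy(),
                       variables=list(table.variables))


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Numeric model-ready matrix plus the train-fitted encoding state."""

    frame: pd.DataFrame
    fit_state: dict

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    def to_numpy(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


class Encoder:
    """Variable encoder with training-set-only fit state.

    binary -> one 0/1 column; categorical -> one indicator column per category
    (categories taken from the variable declaration if present, otherwise from the
    training rows); continuous -> passthrough, optionally centered/scaled with
    training-row mean/SD. Missing source values propagate to NaN in every
    derived column. Categories unseen at fit time encode to an all-zeros
    indicator group (logged, never raised).
    """

    def __init__(self, variables: list[VariableSpec], standardize: bool = False):
        self.variables = list(variables)
        self.standardize = standardize
        self.state_: dict[str, dict] = {}

    def fit(self, table: CohortTable, train_ids) -> "Encoder":
        train = table.values.loc[list(train_ids)]
        self.state_ = {}
        for spec in self.variables:
            col = train[spec.name]
            st: dict = {"kind": spec.kind}
            if spec.kind == "categorical":
                if spec.categories:
                    st["categories"] = list(spec.categories)
                else:
                    st["categories"] = sorted(set(col.dropna().astype(str)))
            elif spec.kind == "continuous" and self.standardize:
                vals = col.dropna().to_numpy(dtype=float)
                mean = float(np.mean(vals)) if vals.size else 0.0
                sd = float(np.std(vals)) if vals.size else 1.0
                st["mean"], st["sd"] = mean, (sd if sd > 0 else 1.0)
            self.state_[spec.name] = st
        return self

    def transform(self, table: CohortTable) -> DesignMatrix:
        if not self.state_:
            raise RuntimeError("Encoder.transform called before fit")
        cols: dict[str, np.ndarray] = {}
        for spec in self.variables:
            st = self.state_[spec.name]
            col = table.values[spec.name]
            if spec.kind == "categorical":
                raw = col.astype(object)
                missing = col.isna().to_numpy()
                observed = raw.where(col.isna(), raw.astype(str))
                known = set(st["categories"])
                unseen = set(observed.dropna()) - known
                if unseen:
                    logger.warning(
                        "variable %r: categories %s unseen at fit time encode to all zeros",
                        spec.name, sorted(unseen),
                    )
                for cat in st["categories"]:
                    ind = (observed == cat).to_numpy(dtype=float)
                    ind[missing] = np.nan
                    cols[f"{spec.name}={cat}"] = ind
            else:
                vals = col.to_numpy(dtype=float)
                if spec.kind == "continuous" and self.standardize:
                    vals = (vals - st["mean"]) / st["sd"]
                cols[spec.name] = vals
        frame = pd.DataFrame(cols, index=table.values.index)
        return DesignMatrix(frame=frame, fit_state={k: dict(v) for k, v in self.state_.items()})

    def fit_transform(self, table: CohortTable, train_ids) -> DesignMatrix:
        return self.fit(table, train_ids).transform(table)


def encode(table: CohortTable, train_ids, standardize: bool = False) -> DesignMatrix:
    """Encode a cohort table with all fit statistics taken from ``train_ids``."""
    missing = set(train_ids) - set(table.sample_ids)
    if missing:
        raise ValueError(f"train_ids not in table: {sorted(missing)[:5]}")
    return Encoder(table.variables, standardize=standardize).fit_transform(table, train_ids)


def decode_onehot(matrix: DesignMatrix, variable: str) -> pd.Series:
    """Recover categorical labels from an indicator group (inverse of encode)."""
    st = matrix.fit_state[variable]
    cats = st["categories"]
    sub = matrix.frame[[f"{variable}={c}" for c in cats]]
    out = pd.Series(pd.NA, index=sub.index, dtype=object)
    arr = sub.to_numpy()
    hit = np.nanargmax(np.where(np.isnan(arr), -1.0, arr), axis=1)
    non_missing = ~np.isnan(arr).any(axis=1)
    has_one = np.nan_to_num(arr, nan=0.0).sum(axis=1) > 0
    ok = non_missing & has_one
    out[ok] = [cats[i] for i in hit[ok]]
    return out


# ---------------------------------------------------------------------------
# stage eligibility
# ---------------------------------------------------------------------------


def block_presence(
    table: CohortTable, partition: ModalityPartition, rule: str = "all"
) -> pd.DataFrame:
    """Sample x block boolean frame of modality availability.

    rule='all': a block is present iff every one of its variables is observed
    (default; missingness is modality-level). rule='any': at least one variable
    observed counts as present (permissive mode).
    """
    if rule not in ("all", "any"):
        raise ValueError(f"completeness rule must be 'all' or 'any', got {rule!r}")
    observed = table.values.notna()
    cols = {}
    for name, vs in partition.blocks:
        sub = observed[list(vs)]
        cols[name] = sub.all(axis=1) if rule == "all" else sub.any(axis=1)
    return pd.DataFrame(cols, index=table.values.index)


def stage_eligible(
    table: CohortTable, partition: ModalityPartition, t: int, rule: str = "all"
) -> list:
    """Sample ids observed for every block 1..t — the stage-t training set."""
    if not 1 <= t <= partition.T:
        raise ValueError(f"stage index t must be in [1, {partition.T}], got {t}")
    presence = block_presence(table, partition, rule=rule)
    ok = presence.iloc[:, :t].all(axis=1)
    return list(presence.index[ok])


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------


def oversample_indices(labels, seed: int) -> np.ndarray:
    """Row indices that balance classes by duplicating minority rows.

    Minority rows are drawn uniformly with replacement until both class counts
    equal the majority count; majority rows and row order of the originals are
    untouched. Deterministic for a fixed seed.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SingleClassError(
            f"oversampling requires both classes, got only class {classes.tolist()}"
        )
    rng = np.random.default_rng(seed)
    majority = counts.max()
    idx = np.arange(len(y))
    extra = []
    for cls, cnt in zip(classes, counts):
        if cnt < majority:
            pool = idx[y == cls]
            extra.append(rng.choice(pool, size=majority - cnt, replace=True))
    if not extra:
        return idx
    return np.concatenate([idx] + extra)


def oversample(matrix: DesignMatrix, labels, seed: int) -> tuple[DesignMatrix, np.ndarray]:
    """Balanced copy of a design matrix (see :func:`oversample_indices`)."""
    idx = oversample_indices(labels, seed)
    y = np.asarray(labels, dtype=int)
    frame = matrix.frame.iloc[idx]
    return DesignMatrix(frame=frame, fit_state=matrix.fit_state), y[idx]
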