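"""Domain types and dataset-subsetting primitives shared by all learners.

A :class:`DiscreteDataset` holds a table of discrete (integer-coded) feature
values plus a binary (or K-ary) target column.  All learners operate on
subsets of a training dataset obtained by conjunctive filtering — "the
individuals that satisfy the path grown so far" — so subsetting must be
cheap: rows are numpy code arrays and subsets share the schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  #: integer code for a missing cell

__all__ = [
    "MISSING",
    "VariableSpec",
    "ScoringConfig",
    "DiscreteDataset",
    "PersonInstance",
    "GrowthStep",
    "GrowthTrace",
    "DecisionPathModel",
    "SchemaError",
    "class_counts",
    "filter_matching",
    "split_by_feature",
]


class SchemaError(ValueError):
    """A value or variable not admitted by the dataset schema."""


@dataclass(frozen=True)
class VariableSpec:
    """One column: its name, kind, and ordered set of admissible values.

    For continuous variables the domain is empty until discretization
    assigns bin labels; discrete learners reject continuous columns.
    """

    name: str
    kind: str = "discrete"  # "discrete" | "continuous"
    domain: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise SchemaError(f"unknown variable kind {self.kind!r}")
        if self.kind == "discrete":
            if len(self.domain) == 0:
                raise SchemaError(f"discrete variable {self.name!r} has empty domain")
            if len(set(self.domain)) != len(self.domain):
                raise SchemaError(f"duplicate domain values for {self.name!r}")

    def code_of(self, value) -> int:
        try:
            return self.domain.index(value)
        except ValueError:
            raise SchemaError(
                f"value {value!r} not in domain of variable {self.name!r}"
            ) from None


@dataclass(frozen=True)
class ScoringConfig:
    """Dirichlet smoothing configuration.

    ``pess`` is the prior equivalent sample size: the total prior mass
    alpha spread uniformly over the K target values (alpha_k = pess/K).
    In the two-sample split score each sample gets alpha_jk = 1/K per
    class, hence alpha_j = 1, matching the non-informative prior used
    throughout the experiments (pess = 1).
    """

    pess: float = 1.0

    def __post_init__(self) -> None:
        if not self.pess > 0:
            raise ValueError("pess must be > 0")

    def alpha_k(self, k_values: int) -> float:
        return self.pess / k_values

    def alpha_jk(self, k_values: int) -> float:
        # prior per class within each of the two split samples
        return 1.0 / k_values


class DiscreteDataset:
    """Rows of integer-coded discrete values plus a target column.

    Parameters
    ----------
    schema : sequence of VariableSpec
        Predictor variables, in column order.
    target : VariableSpec
        The target variable; ``positive`` designates the positive value.
    X : (n, p) int array
        Predictor codes (index into each variable's domain); -1 = missing.
    y : (n,) int array
        Target codes.  Rows with missing target must be dropped before
        construction (see :meth:`from_dataframe`, which reports them).
    """

    def __init__(
        self,
        schema: Sequence[VariableSpec],
        target: VariableSpec,
        X: np.ndarray,
        y: np.ndarray,
        positive: object | None = None,
        n_dropped_missing_target: int = 0,
    ) -> None:
        self.schema = list(schema)
        self.target = target
        self.X = np.asarray(X, dtype=np.int32)
        self.y = np.asarray(y, dtype=np.int32)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.schema):
            raise SchemaError("X shape does not match schema")
        if self.y.shape[0] != self.X.shape[0]:
            raise SchemaError("X and y row counts differ")
        if len(target.domain) < 2:
            raise SchemaError("target domain must have at least 2 values")
        if self.y.size and (self.y.min() < 0 or self.y.max() >= len(target.domain)):
            raise SchemaError("unknown target value code")
        self.positive = positive if positive is not None else target.domain[-1]
        self.positive_index = target.code_of(self.positive)
        self.n_dropped_missing_target = n_dropped_missing_target
        self._index = {v.name: i for i, v in enumerate(self.schema)}

    # -- construction -------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        target: str,
        positive: object | None = None,
        missing_markers: Iterable[object] = ("", "?", "NA"),
    ) -> "DiscreteDataset":
        """Encode a pandas frame of discrete values.

        Domains are the sorted unique non-missing values per column.
        Rows whose target is missing are dropped (their count is kept on
        the returned dataset).
        """
        if target not in df.columns:
            raise SchemaError(f"target column {target!r} absent")
        df = df.copy()
        markers = set(missing_markers)
        for c in df.columns:
            df[c] = df[c].map(lambda v: np.nan if (pd.isna(v) or v in markers) else v)
        tmask = df[target].notna()
        n_dropped = int((~tmask).sum())
        df = df.loc[tmask]

        def spec_for(name: str) -> VariableSpec:
            vals = sorted(df[name].dropna().unique(), key=lambda v: (str(type(v)), v))
            return VariableSpec(name=name, kind="discrete", domain=tuple(vals))

        pred_names = [c for c in df.columns if c != target]
        schema = [spec_for(c) for c in pred_names]
        tspec = spec_for(target)
        X = np.full((len(df), len(schema)), MISSING, dtype=np.int32)
        for j, v in enumerate(schema):
            codes = {val: i for i, val in enumerate(v.domain)}
            col = df[v.name]
            X[:, j] = [MISSING if pd.isna(x) else codes[x] for x in col]
        tcodes = {val: i for i, val in enumerate(tspec.domain)}
        y = np.array([tcodes[x] for x in df[target]], dtype=np.int32)
        return cls(schema, tspec, X, y, positive=positive,
                   n_dropped_missing_target=n_dropped)

    def to_dataframe(self) -> pd.DataFrame:
        """Decode back to labels (missing -> NaN)."""
        out = {}
        for j, v in enumerate(self.schema):
            dom = np.asarray(v.domain, dtype=object)
            col = np.where(self.X[:, j] >= 0, dom[np.clip(self.X[:, j], 0, None)], None)
            out[v.name] = col
        tdom = np.asarray(self.target.domain, dtype=object)
        out[self.target.name] = tdom[self.y]
        return pd.DataFrame(out)

    # -- basic accessors ----------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.target.domain)

    def __len__(self) -> int:
        return self.n_rows

    def column_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def variable(self, name: str) -> VariableSpec:
        return self.schema[self.column_index(name)]

    def subset(self, mask_or_idx) -> "DiscreteDataset":
        sub = DiscreteDataset.__new__(DiscreteDataset)
        sub.schema = self.schema
        sub.target = self.target
        sub.X = self.X[mask_or_idx]
        sub.y = self.y[mask_or_idx]
        sub.positive = self.positive
        sub.positive_index = self.positive_index
        sub.n_dropped_missing_target = 0
        sub._index = self._index
        return sub

    def is_pure(self) -> bool:
        """All remaining individuals share the same target value."""
        return self.n_rows > 0 and bool((self.y == self.y[0]).all())


@dataclass(frozen=True)
class PersonInstance:
    """One test person's variable -> value assignment; values may be missing.

    Stored as codes aligned to a dataset schema; carries no target value.
    """

    codes: np.ndarray  # (p,) int, MISSING where unobserved
    schema: tuple = field(default=(), compare=False)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object], data: DiscreteDataset) -> "PersonInstance":
        codes = np.full(len(data.schema), MISSING, dtype=np.int32)
        for name, value in mapping.items():
            if name == data.target.name:
                continue
            j = data.column_index(name)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                continue
            codes[j] = data.schema[j].code_of(value)
        return cls(codes=codes, schema=tuple(data.schema))

    @classmethod
    def from_row(cls, data: DiscreteDataset, i: int) -> "PersonInstance":
        return cls(codes=data.X[i].copy(), schema=tuple(data.schema))

    def observed_indices(self) -> np.ndarray:
        return np.nonzero(self.codes != MISSING)[0]


@dataclass(frozen=True)
class GrowthStep:
    variable: str
    value: object
    score: float
    n_matching: int  # subgroup size after restricting to the new feature


@dataclass
class GrowthTrace:
    """Per-step record of the greedy growth phase, consumed by pruning."""

    criterion: str
    steps: list = field(default_factory=list)

    def append(self, step: GrowthStep) -> None:
        if not np.isfinite(step.score):
            raise ValueError("trace scores must be finite")
        self.steps.append(step)

    def __len__(self) -> int:
        return len(self.steps)

    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.steps], dtype=float)


@dataclass
class DecisionPathModel:
    """A fitted decision path: the pair (S, theta).

    ``path`` is the ordered conjunct list [(variable, value), ...] — every
    value equals the test person's observed value for that variable.
    ``theta`` is the smoothed target distribution estimated from the
    training individuals matching the path; ``support_counts`` are their
    per-class counts.
    """

    path: list
    theta: np.ndarray
    support_counts: np.ndarray
    trace: GrowthTrace
    target: VariableSpec
    positive_index: int
    config: ScoringConfig = field(default_factory=ScoringConfig)

    def __post_init__(self) -> None:
        names = [v for v, _ in self.path]
        if len(set(names)) != len(names):
            raise ValueError("path variables must be distinct")
        if not np.isclose(self.theta.sum(), 1.0):
            raise ValueError("theta must sum to 1")


# -- subsetting operations --------------------------------------------


def class_counts(data: DiscreteDataset) -> np.ndarray:
    """Per-target-value counts (N_1, ..., N_K), in target-domain order."""
    return np.bincount(data.y, minlength=data.n_classes).astype(np.int64)


def _conjunct_mask(data: DiscreteDataset, conjuncts) -> np.ndarray:
    mask = np.ones(data.n_rows, dtype=bool)
    for variable, value in conjuncts:
        j = data.column_index(variable)
        code = data.schema[j].code_of(value)
        mask &= data.X[:, j] == code  # missing (-1) never equals a code
    return mask


def filter_matching(data: DiscreteDataset, conjuncts) -> DiscreteDataset:
    """Rows satisfying every (variable, value) conjunct.

    A row with a missing value for a conjunct variable does not match.
    The empty conjunction is vacuously true.
    """
    return data.subset(_conjunct_mask(data, conjuncts))


def split_by_feature(data: DiscreteDataset, variable: str, value) -> tuple:
    """Partition into (rows where variable == value, all remaining rows).

    The second part collects non-matching rows including those missing the
    variable; the two parts always partition the input.
    """
    mask = _conjunct_mask(data, [(variable, value)])
    return data.subset(mask), data.subset(~mask)
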