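"""Tabular data model: schema declaration, CSV loading, seeded splits, design encoding.

The data model separates three column roles: a binary outcome, declared
*sensitive* attributes (race, sex, ...) whose influence is audited, and
*less-sensitive* predictors.  Sensitive columns excluded from a model's
design matrix are retained in the :class:`Dataset` so subgroup fairness can
still be evaluated against them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .glm import ExclusionCase

logger = logging.getLogger(__name__)

SPLIT_NAMES = ("train", "validation", "test")
INTERCEPT = "(Intercept)"


class SchemaError(ValueError):
    """A column declaration is inconsistent or missing from the data."""


class ValidationError(ValueError):
    """Data values violate the declared schema."""


@dataclass(frozen=True)
class Schema:
    """Column roles for a modeling dataset.

    Parameters
    ----------
    outcome : str
        Name of the binary (0/1) outcome column.
    sensitive : tuple of str
        Ordered sensitive attribute names (the audited variables).
    predictors : tuple of str
        Ordered less-sensitive predictor names.
    categorical_levels : mapping
        For every categorical column (sensitive or predictor), its ordered
        levels; the first level is the dummy-coding reference.
    """

    outcome: str
    sensitive: tuple[str, ...]
    predictors: tuple[str, ...]
    categorical_levels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensitive", tuple(self.sensitive))
        object.__setattr__(self, "predictors", tuple(self.predictors))
        object.__setattr__(
            self,
            "categorical_levels",
            {k: tuple(str(x) for x in v) for k, v in dict(self.categorical_levels).items()},
        )
        if self.outcome in self.sensitive or self.outcome in self.predictors:
            raise SchemaError(f"outcome column {self.outcome!r} reused as covariate")
        overlap = set(self.sensitive) & set(self.predictors)
        if overlap:
            raise SchemaError(f"columns declared both sensitive and predictor: {sorted(overlap)}")
        if len(set(self.sensitive)) != len(self.sensitive):
            raise SchemaError("duplicate sensitive column names")
        if len(set(self.predictors)) != len(self.predictors):
            raise SchemaError("duplicate predictor column names")
        for col, levels in self.categorical_levels.items():
            if col not in self.sensitive and col not in self.predictors:
                raise SchemaError(f"categorical_levels declares unknown column {col!r}")
            if len(levels) < 2:
                raise SchemaError(f"categorical column {col!r} needs >=2 levels")
            if len(set(levels)) != len(levels):
                raise SchemaError(f"categorical column {col!r} has duplicate levels")

    @property
    def columns(self) -> tuple[str, ...]:
        return (self.outcome, *self.sensitive, *self.predictors)

    def is_categorical(self, name: str) -> bool:
        return name in self.categorical_levels

    def reference_level(self, name: str) -> str:
        return self.categorical_levels[name][0]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "sensitive": list(self.sensitive),
            "predictors": list(self.predictors),
            "categorical_levels": {k: list(v) for k, v in self.categorical_levels.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Schema":
        return cls(
            outcome=d["outcome"],
            sensitive=tuple(d["sensitive"]),
            predictors=tuple(d["predictors"]),
            categorical_levels={k: tuple(v) for k, v in d.get("categorical_levels", {}).items()},
        )


@dataclass
class Dataset:
    """Validated rows plus schema and (optionally) a train/validation/test tag per row."""

    frame: pd.DataFrame
    schema: Schema
    split_labels: pd.Series | None = None

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def outcome(self) -> np.ndarray:
        return self.frame[self.schema.outcome].to_numpy(dtype=int)

    def subset(self, split: str) -> "Dataset":
        """Rows carrying the given split tag, as a new Dataset (index reset)."""
        if self.split_labels is None:
            raise ValueError("dataset has no split labels; call split_dataset first")
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        mask = (self.split_labels == split).to_numpy()
        return Dataset(self.frame.loc[mask].reset_index(drop=True), self.schema, None)

    def with_split(self, labels: pd.Series) -> "Dataset":
        return replace(self, split_labels=labels)


@dataclass
class DesignMatrix:
    """Intercept + dummy-coded categoricals (reference omitted) + continuous columns.

    ``register`` maps every non-intercept matrix column back to the schema
    column it came from (dummy columns map to their categorical variable).
    """

    X: np.ndarray
    columns: tuple[str, ...]
    register: dict[str, str]
    case: "ExclusionCase | None" = None

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


def _validate_frame(frame: pd.DataFrame, schema: Schema, missing_policy: str) -> pd.DataFrame:
    for col in schema.columns:
        if col not in frame.columns:
            raise SchemaError(f"required column {col!r} missing from data")
    frame = frame[list(schema.columns)].copy()

    # outcome: reject rows with missing outcome, then enforce {0,1}
    miss_y = frame[schema.outcome].isna()
    if miss_y.any():
        logger.warning("dropping %d rows with missing outcome", int(miss_y.sum()))
        frame = frame.loc[~miss_y]
    y = pd.to_numeric(frame[schema.outcome], errors="coerce")
    bad = ~y.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"outcome column {schema.outcome!r} has non-binary value "
            f"{frame[schema.outcome].iloc[row]!r} at row {frame.index[row]}"
        )
    frame[schema.outcome] = y.astype(int)

    # covariates: missing-value policy
    covars = list(schema.sensitive) + list(schema.predictors)
    miss = frame[covars].isna().any(axis=1)
    if miss.any():
        if missing_policy == "drop":
            logger.warning("dropping %d rows with missing covariates", int(miss.sum()))
            frame = frame.loc[~miss]
        else:
            raise ValidationError(f"{int(miss.sum())} rows have missing covariates (policy={missing_policy})")

    # categorical levels must be declared
    for col, levels in schema.categorical_levels.items():
        vals = frame[col].astype(str)
        undeclared = ~vals.isin(levels)
        if undeclared.any():
            row = frame.index[np.flatnonzero(undeclared.to_numpy())[0]]
            raise ValidationError(
                f"column {col!r} has undeclared level {vals.loc[row]!r} at row {row}"
            )
        frame[col] = vals
    return frame.reset_index(drop=True)


def load_dataset(path, schema: Schema, missing_policy: str = "drop") -> Dataset:
    """Read a CSV (header row required) and validate it against *schema*."""
    frame = pd.read_csv(path)
    return Dataset(_validate_frame(frame, schema, missing_policy), schema)


def from_dataframe(frame: pd.DataFrame, schema: Schema, missing_policy: str = "drop") -> Dataset:
    """Validate an in-memory table against *schema*."""
    return Dataset(_validate_frame(frame, schema, missing_policy), schema)


def _allocate_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n rows to the split fractions."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_dataset(
    data: Dataset,
    fractions: Sequence[float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    stratify: bool = False,
) -> Dataset:
    """Random row partition into train/validation/test with exact apportioned sizes.

    The same seed always yields the same partition.  With ``stratify=True``
    the partition is performed within each outcome class.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("need three positive fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = data.n_rows
    labels = np.empty(n, dtype=object)
    rng = np.random.default_rng(seed)

    def assign(indices: np.ndarray) -> None:
        counts = _allocate_counts(len(indices), fractions)
        perm = rng.permutation(indices)
        start = 0
        for name, c in zip(SPLIT_NAMES, counts):
            labels[perm[start : start + c]] = name
            start += c

    if stratify:
        y = data.outcome
        for cls in (0, 1):
            assign(np.flatnonzero(y == cls))
    else:
        assign(np.arange(n))

    series = pd.Series(labels, index=data.frame.index, name="split")
    sizes = series.value_counts()
    for name in SPLIT_NAMES:
        if sizes.get(name, 0) == 0:
            raise ValueError(f"split {name!r} is empty: dataset too small for fractions {fractions}")
    logger.info("split sizes: %s (seed=%d)", {k: int(sizes[k]) for k in SPLIT_NAMES}, seed)
    return data.with_split(series)


def encode_design(data: Dataset, schema: Schema, case: "ExclusionCase | None" = None) -> DesignMatrix:
    """Build the model design matrix for one sensitive-variable exclusion case.

    Column order is fixed: intercept, retained sensitive variables in schema
    order, then predictors in schema order.  Categorical columns are dummy
    coded with the declared reference level omitted; excluded sensitive
    columns are simply absent (but stay in ``data`` for subgroup audits).
    """
    retained = tuple(schema.sensitive) if case is None else tuple(case.retained)
    unknown = set(retained) - set(schema.sensitive)
    if unknown:
        raise SchemaError(f"exclusion case retains undeclared sensitive columns: {sorted(unknown)}")

    cols: list[np.ndarray] = [np.ones(data.n_rows)]
    names: list[str] = [INTERCEPT]
    register: dict[str, str] = {}

    ordered = [s for s in schema.sensitive if s in retained] + list(schema.predictors)
    for col in ordered:
        if schema.is_categorical(col):
            vals = data.frame[col].astype(str)
            observed = vals.nunique()
            if observed < 2:
                raise ValidationError(
                    f"categorical column {col!r} is constant in the data; its coefficients are inestimable"
                )
            for level in schema.categorical_levels[col][1:]:
                name = f"{col}[{level}]"
                cols.append((vals == level).to_numpy(dtype=float))
                names.append(name)
                register[name] = col
        else:
            name = col
            cols.append(pd.to_numeric(data.frame[col]).to_numpy(dtype=float))
            names.append(name)
            register[name] = col

    X = np.column_stack(cols)
    return DesignMatrix(X=X, columns=tuple(names), register=register, case=case)
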