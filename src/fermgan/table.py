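"""Feature tables, min-max scaling and the train/validation/test split.

The universal data currency of the package is the :class:`FeatureTable`: a
4-column record of fermentation runs — time (h), temperature (°C), starter
culture dosage (v/v) and alcohol content (°P) — plus a provenance label
(1 = real/experimental, 0 = synthetic).  All downstream stages (adversarial
training, fidelity testing, surrogate modelling, attribution) consume and
produce this structure.

Scaling follows the min-max convention: each feature is mapped affinely so
that its observed minimum and maximum land on a target range, (-1, 1) by
default, matching the tanh output activation of the generator network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FEATURE_COLUMNS: tuple[str, ...] = ("time", "temperature", "dose", "alcohol")
PREDICTOR_COLUMNS: tuple[str, ...] = ("time", "temperature", "dose")
TARGET_COLUMN: str = "alcohol"
LABEL_COLUMN: str = "label"

REAL_LABEL = 1
SYNTHETIC_LABEL = 0


class SchemaError(ValueError):
    """A table does not have the expected columns."""


class ParseError(ValueError):
    """A table cell could not be parsed as a number."""


class DegenerateFeatureError(ValueError):
    """A feature is constant where a non-zero range is required."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass(frozen=True)
class FeatureTable:
    """Rows of (time, temperature, dose, alcohol) with provenance labels.

    Parameters
    ----------
    values : ndarray, shape (n, 4)
        Feature values in the fixed column order of ``FEATURE_COLUMNS``.
    labels : ndarray, shape (n,)
        Provenance per row: 1 for real (experimental), 0 for synthetic.
    """

    values: np.ndarray
    labels: np.ndarray
    column_names: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if values.ndim != 2 or values.shape[1] != len(self.column_names):
            raise SchemaError(
                f"expected {len(self.column_names)} feature columns, got shape {values.shape}"
            )
        if len(self.column_names) != 4:
            raise SchemaError("a FeatureTable has exactly 4 feature columns")
        if labels.shape != (values.shape[0],):
            raise SchemaError("labels must be one per row")
        if not np.isfinite(values).all():
            raise ParseError("table contains missing or non-finite values")
        if not np.isin(labels, (REAL_LABEL, SYNTHETIC_LABEL)).all():
            raise SchemaError("labels must be 0 (synthetic) or 1 (real)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "column_names", tuple(self.column_names))

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.column_names.index(name)
        except ValueError:
            raise SchemaError(f"no such column: {name!r}") from None
        return self.values[:, j]

    @property
    def predictors(self) -> np.ndarray:
        """The (n, 3) matrix of process factors (time, temperature, dose)."""
        return self.values[:, :3]

    @property
    def target(self) -> np.ndarray:
        """The alcohol content column (°P)."""
        return self.values[:, 3]

    def take(self, indices: Sequence[int] | np.ndarray) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(self.values[idx], self.labels[idx], self.column_names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.column_names))
        df[LABEL_COLUMN] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: int | None = None) -> "FeatureTable":
        missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        values = _numeric_block(df, FEATURE_COLUMNS)
        if label is not None:
            labels = np.full(len(df), int(label))
        elif LABEL_COLUMN in df.columns:
            labels = df[LABEL_COLUMN].to_numpy(dtype=int)
        else:
            labels = np.full(len(df), REAL_LABEL)
        return cls(values, labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        if other.column_names != self.column_names:
            raise SchemaError("cannot concatenate tables with different schemas")
        return FeatureTable(
            np.vstack([self.values, other.values]),
            np.concatenate([self.labels, other.labels]),
            self.column_names,
        )


def _numeric_block(df: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    out = np.empty((len(df), len(columns)), dtype=float)
    for j, c in enumerate(columns):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[c].iloc[row]!r} in column {c!r} at row {row}"
            )
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ParseError(f"missing value in column {c!r} at row {row}")
        out[:, j] = col.to_numpy(dtype=float)
    return out


def load_table(path: str | Path, schema: Sequence[str] = FEATURE_COLUMNS) -> FeatureTable:
    """Read a feature table from a CSV file with a header row.

    The file must contain the four feature columns (any extra columns are
    ignored, except an optional ``label`` column carrying provenance).
    Row order is preserved.
    """
    if tuple(schema) != FEATURE_COLUMNS:
        raise SchemaError(f"schema must be {FEATURE_COLUMNS}")
    df = pd.read_csv(path)
    return FeatureTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# Min-max scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature affine map x' = low + (high-low) * (x - min) / (max - min)."""

    feature_mins: np.ndarray
    feature_maxs: np.ndarray
    feature_range: tuple[float, float] = (-1.0, 1.0)
    column_names: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_mins", np.asarray(self.feature_mins, dtype=float))
        object.__setattr__(self, "feature_maxs", np.asarray(self.feature_maxs, dtype=float))
        object.__setattr__(self, "column_names", tuple(self.column_names))
        if (self.feature_maxs < self.feature_mins).any():
            raise ValueError("feature max must be >= min")
        low, high = self.feature_range
        if not high > low:
            raise ConfigError("scaler range must satisfy high > low")

    @property
    def scale(self) -> np.ndarray:
        low, high = self.feature_range
        return (high - low) / (self.feature_maxs - self.feature_mins)

    def transform(self, values: np.ndarray) -> np.ndarray:
        low, _ = self.feature_range
        return low + (np.asarray(values, float) - self.feature_mins) * self.scale

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        low, _ = self.feature_range
        return self.feature_mins + (np.asarray(values, float) - low) / self.scale

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_mins": self.feature_mins.tolist(),
            "feature_maxs": self.feature_maxs.tolist(),
            "range": list(self.feature_range),
            "columns": list(self.column_names),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScalerParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            np.asarray(payload["feature_mins"], float),
            np.asarray(payload["feature_maxs"], float),
            tuple(payload["range"]),
            tuple(payload.get("columns", FEATURE_COLUMNS)),
        )


def fit_scaler(
    table: FeatureTable, feature_range: tuple[float, float] = (-1.0, 1.0)
) -> ScalerParams:
    """Fit per-feature min-max parameters so observed min -> low, max -> high."""
    if len(table) < 2:
        raise ValueError("need at least 2 rows to fit a scaler")
    mins = table.values.min(axis=0)
    maxs = table.values.max(axis=0)
    degenerate = np.flatnonzero(maxs == mins)
    if degenerate.size:
        names = ", ".join(table.column_names[j] for j in degenerate)
        raise DegenerateFeatureError(f"constant feature(s): {names}")
    return ScalerParams(mins, maxs, feature_range, table.column_names)


def apply_scaler(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    if table.column_names != params.column_names:
        raise SchemaError("scaler was fitted on a table with a different schema")
    return FeatureTable(params.transform(table.values), table.labels, table.column_names)


def invert_scaler(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    if table.column_names != params.column_names:
        raise SchemaError("scaler was fitted on a table with a different schema")
    return FeatureTable(params.inverse_transform(table.values), table.labels, table.column_names)


# ---------------------------------------------------------------------------
# Train / validation / test split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Fractions of the 58/38/4 train/validation/test split and its seed."""

    fractions: tuple[float, float, float] = (0.58, 0.38, 0.04)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigError(f"split fractions must sum to 1, got {self.fractions}")
        if any(not (0.0 < f < 1.0) for f in self.fractions):
            raise ConfigError("each split fraction must lie in (0, 1)")


def split_sizes(n: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n rows to the three parts.

    Remaining seats after flooring go to the largest fractional remainders;
    ties are resolved in favour of the later part (test, then validation,
    then train).  The test part is guaranteed at least one row.
    """
    exact = np.asarray(fractions, float) * n
    base = np.floor(exact).astype(int)
    remainder = exact - base
    seats = n - int(base.sum())
    # stable sort on (-remainder, -index): later parts win ties
    order = sorted(range(len(fractions)), key=lambda i: (-remainder[i], -i))
    for i in order[:seats]:
        base[i] += 1
    if base[2] == 0:
        donor = int(np.argmax(base[:2]))
        base[donor] -= 1
        base[2] = 1
    return int(base[0]), int(base[1]), int(base[2])


def split_data(
    table: FeatureTable, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Partition a table into disjoint train/validation/test tables.

    Rows are assigned by uniform sampling without replacement under the
    spec's seed; the same seed always yields the same membership.
    """
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 rows to split")
    n_train, n_val, n_test = split_sizes(n, spec.fractions)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    return (
        table.take(perm[:n_train]),
        table.take(perm[n_train : n_train + n_val]),
        table.take(perm[n_train + n_val :]),
    )
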