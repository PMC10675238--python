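"""Batch-process data containers, CSV I/O, splitting, scaling and error metrics.

A :class:`BatchDataset` is a tidy table of one row per (batch, time
point): a matrix of auxiliary (environmental) variables that are cheap
to measure online, and one or more target columns holding the key
biochemical parameters the soft sensor predicts (biomass X, substrate
S, product activity P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSchema",
    "BatchDataset",
    "Scaler",
    "SchemaError",
    "DataError",
    "read_batches",
    "write_batches",
    "split_by_batch",
    "rmse",
    "max_abs_error",
]


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class DataError(ValueError):
    """A cell violates the dataset invariants (NaN, bad time order, ...)."""


@dataclass
class ColumnSchema:
    """Maps CSV columns onto roles."""

    batch: str = "batch_id"
    time: str = "time_index"
    aux: tuple[str, ...] = ()
    targets: tuple[str, ...] = ()


@dataclass
class BatchDataset:
    """Rows of (batch, time) with auxiliary matrix and target matrix.

    Invariants: no missing values, rows sorted by (batch, time),
    time_index strictly increasing within a batch.
    """

    batch_id: np.ndarray                 # (n,) int
    time_index: np.ndarray               # (n,) int
    aux: np.ndarray                      # (n, d) float
    targets: np.ndarray                  # (n, q) float
    aux_names: tuple[str, ...] = field(default_factory=tuple)
    target_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.batch_id = np.asarray(self.batch_id, dtype=int)
        self.time_index = np.asarray(self.time_index, dtype=int)
        self.aux = np.atleast_2d(np.asarray(self.aux, dtype=float))
        self.targets = np.atleast_2d(np.asarray(self.targets, dtype=float))
        if self.targets.shape[0] == 1 and self.batch_id.shape[0] > 1:
            self.targets = self.targets.T
        if self.aux.shape[0] == 1 and self.batch_id.shape[0] > 1:
            self.aux = self.aux.T
        if not self.aux_names:
            self.aux_names = tuple(f"x{j}" for j in range(self.aux.shape[1]))
        if not self.target_names:
            self.target_names = tuple(f"y{j}" for j in range(self.targets.shape[1]))
        self.aux_names = tuple(self.aux_names)
        self.target_names = tuple(self.target_names)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n = self.batch_id.shape[0]
        if not (self.time_index.shape[0] == self.aux.shape[0] == self.targets.shape[0] == n):
            raise DataError("row counts of batch_id/time_index/aux/targets disagree")
        if self.aux.shape[1] < 1 or self.targets.shape[1] < 1:
            raise DataError("need at least one auxiliary and one target column")
        if len(self.aux_names) != self.aux.shape[1]:
            raise SchemaError("aux_names length does not match aux width")
        if len(self.target_names) != self.targets.shape[1]:
            raise SchemaError("target_names length does not match targets width")
        for name, mat in (("aux", self.aux), ("targets", self.targets)):
            bad = np.argwhere(~np.isfinite(mat))
            if bad.size:
                r, c = bad[0]
                raise DataError(f"non-finite value in {name} at row {int(r)}, column {int(c)}")
        order = np.lexsort((self.time_index, self.batch_id))
        if not np.array_equal(order, np.arange(n)):
            raise DataError("rows must be sorted by (batch_id, time_index)")
        for b in np.unique(self.batch_id):
            t = self.time_index[self.batch_id == b]
            if np.any(np.diff(t) <= 0):
                raise DataError(f"time_index not strictly increasing within batch {int(b)}")

    # -- views ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.batch_id.shape[0]

    @property
    def batches(self) -> np.ndarray:
        return np.unique(self.batch_id)

    @property
    def n_batches(self) -> int:
        return self.batches.shape[0]

    def target_vector(self, name: str) -> np.ndarray:
        try:
            j = self.target_names.index(name)
        except ValueError as exc:
            raise SchemaError(f"unknown target column {name!r}") from exc
        return self.targets[:, j].copy()

    def aux_matrix(self, names: tuple[str, ...] | list[str] | None = None) -> np.ndarray:
        if names is None:
            return self.aux.copy()
        idx = []
        for name in names:
            try:
                idx.append(self.aux_names.index(name))
            except ValueError as exc:
                raise SchemaError(f"unknown auxiliary column {name!r}") from exc
        return self.aux[:, idx].copy()

    def with_time_feature(self, name: str = "time_index") -> "BatchDataset":
        """Return a copy with the time index appended as an auxiliary column."""
        if name in self.aux_names:
            return self
        return BatchDataset(
            batch_id=self.batch_id.copy(),
            time_index=self.time_index.copy(),
            aux=np.column_stack([self.aux, self.time_index.astype(float)]),
            targets=self.targets.copy(),
            aux_names=self.aux_names + (name,),
            target_names=self.target_names,
        )

    def select_batches(self, batch_ids: np.ndarray) -> "BatchDataset":
        mask = np.isin(self.batch_id, batch_ids)
        return BatchDataset(
            batch_id=self.batch_id[mask],
            time_index=self.time_index[mask],
            aux=self.aux[mask],
            targets=self.targets[mask],
            aux_names=self.aux_names,
            target_names=self.target_names,
        )

    # -- frame conversion ----------------------------------------------
    def to_frame(self, schema: ColumnSchema | None = None) -> pd.DataFrame:
        schema = schema or ColumnSchema(aux=self.aux_names, targets=self.target_names)
        df = pd.DataFrame({schema.batch: self.batch_id, schema.time: self.time_index})
        for j, name in enumerate(self.aux_names):
            df[name] = self.aux[:, j]
        for j, name in enumerate(self.target_names):
            df[name] = self.targets[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, schema: ColumnSchema) -> "BatchDataset":
        for col in (schema.batch, schema.time, *schema.aux, *schema.targets):
            if col not in df.columns:
                raise SchemaError(f"missing column {col!r}")
        df = df.sort_values([schema.batch, schema.time], kind="stable").reset_index(drop=True)
        for col in (*schema.aux, *schema.targets):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
            if bad.size:
                raise DataError(f"NaN or non-numeric value in column {col!r} at row {int(bad[0])}")
        return cls(
            batch_id=df[schema.batch].to_numpy(dtype=int),
            time_index=df[schema.time].to_numpy(dtype=int),
            aux=df[list(schema.aux)].to_numpy(dtype=float),
            targets=df[list(schema.targets)].to_numpy(dtype=float),
            aux_names=tuple(schema.aux),
            target_names=tuple(schema.targets),
        )


def read_batches(path, schema: ColumnSchema) -> BatchDataset:
    """Read a header-bearing CSV and validate it against the schema."""
    df = pd.read_csv(path)
    return BatchDataset.from_frame(df, schema)


def write_batches(ds: BatchDataset, path, schema: ColumnSchema | None = None) -> None:
    ds.to_frame(schema).to_csv(path, index=False)


def split_by_batch(ds: BatchDataset, n_train_batches: int) -> tuple[BatchDataset, BatchDataset]:
    """First ``n_train_batches`` (by sorted batch id) become the training
    set, the remainder the test set; no row is lost or duplicated."""
    batches = ds.batches
    if not 0 < n_train_batches < batches.shape[0]:
        raise ValueError(
            f"n_train_batches must be in (0, {batches.shape[0]}), got {n_train_batches}"
        )
    return ds.select_batches(batches[:n_train_batches]), ds.select_batches(batches[n_train_batches:])


@dataclass
class Scaler:
    """Per-column affine scaler fit on training rows only.

    ``zscore`` maps to zero mean / unit sd; ``minmax`` to [0, 1].
    Columns with zero spread are passed through unchanged.
    """

    mode: str = "zscore"
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    _EPS = 1e-12

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.mode == "zscore":
            center = X.mean(axis=0)
            scale = X.std(axis=0, ddof=0)
        elif self.mode == "minmax":
            center = X.min(axis=0)
            scale = X.max(axis=0) - center
        else:
            raise ValueError("mode must be 'zscore' or 'minmax'")
        flat = scale <= self._EPS
        center = np.where(flat, 0.0, center)
        scale = np.where(flat, 1.0, scale)
        self.center, self.scale = center, scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.center is None:
            raise RuntimeError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        return (X - self.center) / self.scale

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if self.center is None:
            raise RuntimeError("scaler not fitted")
        return np.asarray(X, dtype=float) * self.scale + self.center

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def _check_pair(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape[0] == 0 or y.shape[0] != yhat.shape[0]:
        raise ValueError("y and yhat must have equal non-zero lengths")
    return y, yhat


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error sqrt(mean((y - yhat)^2))."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def max_abs_error(y: np.ndarray, yhat: np.ndarray) -> float:
    """Maximum absolute error max|y - yhat|."""
    y, yhat = _check_pair(y, yhat)
    return float(np.max(np.abs(y - yhat)))
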