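"""Core tabular containers: sample-by-variable data blocks and covariate tables.

A :class:`DataBlock` is the unit every other module operates on: an n x p
numeric matrix with unique sample identifiers and unique variable names.
A :class:`ConfoundTable` holds mixed numeric/categorical covariates that are
regressed out of both blocks before any decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["DataBlock", "ConfoundTable", "align_samples"]


def _check_unique(labels, what: str) -> None:
    if len(set(labels)) != len(labels):
        seen, dupes = set(), []
        for x in labels:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass(frozen=True)
class DataBlock:
    """An n x p numeric matrix with sample IDs and variable names.

    Parameters
    ----------
    sample_ids : tuple of str
        Unique, ordered sample identifiers (row labels).
    variable_names : tuple of str
        Unique, ordered variable labels (column labels).
    values : ndarray of shape (n, p)
        Finite float matrix; copied defensively on construction.
    """

    sample_ids: tuple
    variable_names: tuple
    values: np.ndarray

    def __post_init__(self):
        ids = tuple(str(s) for s in self.sample_ids)
        names = tuple(str(v) for v in self.variable_names)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError(f"values must be 2-D, got ndim={vals.ndim}")
        if vals.shape != (len(ids), len(names)):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(ids)} sample_ids x {len(names)} variable_names"
            )
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at sample {ids[bad[0]]!r}, "
                f"variable {names[bad[1]]!r}"
            )
        _check_unique(ids, "sample_ids")
        _check_unique(names, "variable_names")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "variable_names", names)
        object.__setattr__(self, "values", vals.copy())

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "DataBlock":
        """Return a new block with the same labels and different values."""
        return DataBlock(self.sample_ids, self.variable_names, values)

    def to_frame(self, id_col: str = "sample_id") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.variable_names))
        df.insert(0, id_col, list(self.sample_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_col: str = "sample_id") -> "DataBlock":
        if id_col not in df.columns:
            raise ValidationError(f"missing identifier column {id_col!r}")
        ids = tuple(str(s) for s in df[id_col])
        cols = [c for c in df.columns if c != id_col]
        try:
            vals = df[cols].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric data in block: {exc}") from exc
        return cls(ids, tuple(cols), vals)


@dataclass(frozen=True)
class ConfoundTable:
    """An n x q table of covariates, each column numeric or categorical.

    Categorical columns are detected by dtype (object / category / bool) or
    can be forced via ``categorical``. Every categorical column must have at
    least 2 observed levels; no missing values are allowed anywhere.
    """

    sample_ids: tuple
    data: pd.DataFrame
    categorical: tuple = field(default=())

    def __post_init__(self):
        ids = tuple(str(s) for s in self.sample_ids)
        _check_unique(ids, "sample_ids")
        df = self.data.copy()
        if len(df) != len(ids):
            raise ValidationError(
                f"{len(df)} covariate rows for {len(ids)} sample_ids"
            )
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValidationError(f"missing values in covariates {bad}")
        df.index = pd.Index(ids, name="sample_id")
        cat = set(self.categorical)
        for col in df.columns:
            if df[col].dtype == object or isinstance(
                df[col].dtype, pd.CategoricalDtype
            ) or df[col].dtype == bool:
                cat.add(col)
        for col in sorted(cat):
            if col not in df.columns:
                raise ValidationError(f"categorical column {col!r} not in table")
            levels = df[col].astype(str).unique()
            if len(levels) < 2:
                raise ValidationError(
                    f"categorical covariate {col!r} has a single observed level"
                )
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "data", df)
        object.__setattr__(self, "categorical", tuple(sorted(cat)))

    @property
    def numeric_columns(self) -> tuple:
        return tuple(c for c in self.data.columns if c not in self.categorical)

    @property
    def categorical_columns(self) -> tuple:
        return self.categorical

    def reorder(self, sample_ids) -> "ConfoundTable":
        ids = tuple(str(s) for s in sample_ids)
        if set(ids) != set(self.sample_ids):
            raise ValidationError("sample-ID sets differ; cannot reorder confounds")
        df = self.data.loc[list(ids)]
        return ConfoundTable(ids, df.reset_index(drop=True), self.categorical)

    def to_frame(self, id_col: str = "sample_id") -> pd.DataFrame:
        df = self.data.reset_index(drop=True).copy()
        df.insert(0, id_col, list(self.sample_ids))
        return df


def align_samples(x: DataBlock, y: DataBlock, confounds: ConfoundTable | None = None):
    """Join inputs on sample IDs (order of ``x`` wins); refuse silent mismatch.

    Returns re-ordered ``(x, y, confounds)``. Raises if the ID sets differ.
    """
    if set(x.sample_ids) != set(y.sample_ids):
        only_x = set(x.sample_ids) - set(y.sample_ids)
        only_y = set(y.sample_ids) - set(x.sample_ids)
        raise ValidationError(
            f"sample-ID mismatch between blocks: {len(only_x)} only in X, "
            f"{len(only_y)} only in Y"
        )
    if x.sample_ids != y.sample_ids:
        order = {s: i for i, s in enumerate(y.sample_ids)}
        idx = [order[s] for s in x.sample_ids]
        y = DataBlock(x.sample_ids, y.variable_names, y.values[idx])
    if confounds is not None:
        if set(confounds.sample_ids) != set(x.sample_ids):
            raise ValidationError("confound sample IDs do not match the blocks")
        if confounds.sample_ids != x.sample_ids:
            confounds = confounds.reorder(x.sample_ids)
    return x, y, confounds
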