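"""Confound residualization, standardization and collinearity diagnostics.

The pipeline order is fixed: covariates are regressed out of each block
first, then every column is scaled to mean 0 / SD 1 (denominator n-1).
:func:`preprocess_blocks` is the driver that enforces that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .blocks import ConfoundTable, DataBlock
from .errors import ValidationError

__all__ = [
    "DesignMatrix",
    "encode_confounds",
    "residualize",
    "standardize",
    "vif",
    "preprocess_blocks",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class DesignMatrix:
    """Full-column-rank n x (1+d) design with intercept first.

    ``column_labels`` record the source covariate (and level, for one-hot
    columns) so error messages and coefficient tables stay readable.
    """

    values: np.ndarray
    column_labels: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != len(self.column_labels):
            raise ValidationError("design shape does not match its labels")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite value in design matrix")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "column_labels", tuple(self.column_labels))

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _collinear_columns(A: np.ndarray, labels) -> list:
    # pivoted QR: columns with negligible diagonal in R are the redundant ones
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = diag.max() * max(A.shape) * np.finfo(float).eps
    bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= thresh]
    return bad


def encode_confounds(confounds: ConfoundTable) -> DesignMatrix:
    """Build the regression design: intercept, numeric columns, one-hot levels.

    Categorical covariates are reference-coded: levels are sorted
    lexicographically and the first is dropped. Constant numeric columns,
    single-level categoricals and any rank deficiency raise
    :class:`ValidationError`.
    """
    n = len(confounds.sample_ids)
    cols = [np.ones(n)]
    labels = ["intercept"]
    for name in confounds.data.columns:
        if name in confounds.categorical_columns:
            series = confounds.data[name].astype(str)
            levels = sorted(series.unique())
            if len(levels) < 2:
                raise ValidationError(
                    f"categorical covariate {name!r} has a single level"
                )
            for level in levels[1:]:  # drop lexicographically first level
                cols.append((series == level).to_numpy(dtype=float))
                labels.append(f"{name}[{level}]")
        else:
            v = confounds.data[name].to_numpy(dtype=float)
            if np.ptp(v) == 0.0:
                raise ValidationError(f"numeric covariate {name!r} is constant")
            cols.append(v)
            labels.append(name)
    A = np.column_stack(cols)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        bad = _collinear_columns(A, labels)
        raise ValidationError(
            f"confound design is rank deficient; collinear columns: {bad}"
        )
    return DesignMatrix(A, tuple(labels))


def residualize(block: DataBlock, design: DesignMatrix) -> DataBlock:
    """Replace every block column by its least-squares residual on the design.

    Uses an SVD-based (rank-revealing) solve rather than normal equations.
    Residuals are orthogonal to every design column by construction.
    """
    if block.n != design.n:
        raise ValidationError(
            f"block has {block.n} samples but design has {design.n} rows"
        )
    A = design.values
    beta, _, rank, _ = scipy.linalg.lstsq(A, block.values, lapack_driver="gelsd")
    if rank < A.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    return block.with_values(block.values - A @ beta)


def standardize(block: DataBlock) -> DataBlock:
    """Scale each column to mean 0 and sample SD 1 (ddof=1)."""
    vals = block.values
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0.0)
    if zero.size:
        raise ValidationError(
            f"zero-variance column(s): {[block.variable_names[j] for j in zero]}"
        )
    return block.with_values((vals - mu) / sd)


def vif(block: DataBlock) -> np.ndarray:
    """Variance inflation factor per variable: 1 / (1 - R^2_j).

    R^2_j comes from regressing column j on all other columns (with
    intercept). Perfectly collinear variables are flagged with ``+inf``
    rather than raising.
    """
    vals = block.values
    n, p = vals.shape
    if n <= p:
        raise ValidationError(f"need n > p for VIF, got n={n}, p={p}")
    X = vals - vals.mean(axis=0)
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        tss = yj @ yj
        if tss == 0.0:
            raise ValidationError(
                f"constant column {block.variable_names[j]!r} in VIF input"
            )
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            out[j] = 1.0
            continue
        beta, _, _, _ = scipy.linalg.lstsq(others, yj, lapack_driver="gelsd")
        rss = yj - others @ beta
        r2 = 1.0 - (rss @ rss) / tss
        out[j] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return out


def preprocess_blocks(
    x: DataBlock,
    y: DataBlock,
    confounds: ConfoundTable | None = None,
    skip_residualization: bool = False,
):
    """Run the fixed preprocessing order: residualize, then standardize.

    Returns ``(x, y)`` ready for the decomposition module. When
    ``confounds`` is None or ``skip_residualization`` is set, only
    standardization is applied.
    """
    if confounds is not None and not skip_residualization:
        design = encode_confounds(confounds)
        x = residualize(x, design)
        y = residualize(y, design)
    return standardize(x), standardize(y)
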