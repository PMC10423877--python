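"""Permutation-based component significance and explained-variance profiling.

The permutation scheme follows the associative null: rows of the behavior
block are shuffled (brain block untouched), the model is refit from scratch
and the Pearson correlation of each paired score column is recorded.
P-values use the add-one convention ``(1 + #{null >= observed}) / (1 + B)``
so they are bounded below by 1/(B+1) and never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import DataBlock
from .decomposition import CrossFit, fit_method, structure_coefficients
from .errors import ValidationError

__all__ = [
    "PermutationReport",
    "component_rho",
    "permutation_test",
    "explained_variance",
]


@dataclass
class PermutationReport:
    """Observed per-component rho, its permutation null, and p-values."""

    method: str
    B: int
    seed: int
    observed_rho: np.ndarray
    null_rho: np.ndarray  # B x k
    p_values: np.ndarray
    explained_variance_x: np.ndarray
    explained_variance_y: np.ndarray

    @property
    def k(self) -> int:
        return len(self.observed_rho)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "B": self.B,
            "seed": self.seed,
            "observed_rho": self.observed_rho.tolist(),
            "p_values": self.p_values.tolist(),
            "explained_variance_x": self.explained_variance_x.tolist(),
            "explained_variance_y": self.explained_variance_y.tolist(),
            "null_rho": self.null_rho.tolist(),
        }


def component_rho(fit: CrossFit) -> np.ndarray:
    """Pearson correlation of each paired score column (T[:, c], S[:, c])."""
    T, S = fit.T, fit.S
    Tc = T - T.mean(axis=0)
    Sc = S - S.mean(axis=0)
    st, ss = Tc.std(axis=0), Sc.std(axis=0)
    if np.any(st == 0.0) or np.any(ss == 0.0):
        bad = sorted(
            set(np.flatnonzero(st == 0.0)) | set(np.flatnonzero(ss == 0.0))
        )
        raise ValidationError(f"constant score column(s): {bad}")
    return np.sum(Tc * Sc, axis=0) / (len(T) * st * ss)


def explained_variance(fit: CrossFit, X: DataBlock, Y: DataBlock):
    """Per-component fraction of each block's total variance captured.

    The reconstruction of a block from one score column explains
    ``corr(x_j, t_c)^2 * var(x_j)`` of variable j's variance; the fraction
    is the sum over variables divided by the block's total variance.
    Returns ``(fractions_x, fractions_y)``, each length k with entries in
    [0, 1].
    """
    xl, yl = structure_coefficients(fit, X, Y)
    out = []
    for block, load in ((X, xl), (Y, yl)):
        var = block.values.var(axis=0, ddof=1)
        out.append((load**2 * var[:, None]).sum(axis=0) / var.sum())
    return tuple(out)


def permutation_test(
    X: DataBlock,
    Y: DataBlock,
    method: str,
    k: int | None = None,
    B: int = 1000,
    seed: int = 0,
    **fit_kwargs,
) -> PermutationReport:
    """Permutation significance of each of the k components of one method.

    For each of B iterations the rows of Y are permuted by a fresh uniform
    random permutation, the model is refit, and component c's rho in the
    permuted fit is recorded as its null draw (no re-sorting or matching
    across permutations). The identity permutation is not excluded.
    """
    if B < 1:
        raise ValidationError(f"B must be >= 1, got {B}")
    fit = fit_method(method, X, Y, k=k, **fit_kwargs)
    observed = component_rho(fit)
    ev_x, ev_y = explained_variance(fit, X, Y)

    rng = np.random.default_rng(seed)
    null = np.empty((B, fit.k))
    for b in range(B):
        perm = rng.permutation(Y.n)
        Yp = Y.with_values(Y.values[perm])
        null[b] = component_rho(fit_method(method, X, Yp, k=fit.k, **fit_kwargs))
    p = (1.0 + np.sum(null >= observed[None, :], axis=0)) / (1.0 + B)
    return PermutationReport(
        method=fit.method,
        B=B,
        seed=seed,
        observed_rho=observed,
        null_rho=null,
        p_values=p,
        explained_variance_x=ev_x,
        explained_variance_y=ev_y,
    )
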