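"""Two-block cross-decomposition: CCA, PLS-correlation and PLS-regression.

All three methods share one fitted data model (:class:`CrossFit`): weight
matrices ``U`` (p x k) and ``V`` (m x k), score matrices ``T`` and ``S``
computed on column-centered data, a per-component association value whose
meaning depends on the method, and structure-coefficient (loading)
matrices.

Method semantics
----------------
CCA
    maximizes the Pearson *correlation* of paired scores; operates on
    whitened blocks, so it is invariant to any invertible linear re-mixing
    within a block. ``assoc`` holds the canonical correlations.
PLSC
    maximizes the *covariance* of paired scores: one SVD of the sample
    cross-covariance matrix, no deflation; ``assoc`` holds the singular
    values and the weight vectors have unit norm.
PLSR
    asymmetric/predictive PLS2: X-weights are extracted sequentially from
    the deflated cross-covariance, X is deflated by regression on its own
    score, Y is never deflated, and a p x m coefficient matrix ``coef`` is
    exposed for prediction. ``assoc`` holds the sample covariance of each
    paired score column.

Determinism: no randomized initialization anywhere; the sign of every
component is fixed so that the largest-magnitude entry of the Y-side weight
vector is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .blocks import DataBlock
from .errors import NumericalError, ValidationError

__all__ = [
    "CrossFit",
    "fit_cca",
    "fit_plsc",
    "fit_plsr",
    "fit_method",
    "structure_coefficients",
    "predict_plsr",
    "METHODS",
]

METHODS = ("CCA", "PLSC", "PLSR")

_TIE_TOL = 1e-10

@dataclass
class CrossFit:
    """A fitted two-block decomposition.

    Attributes
    ----------
    method : {"CCA", "PLSC", "PLSR"}
    k : int
        Number of components extracted.
    U, V : ndarray
        Brain-side (p x k) and behavior-side (m x k) weight matrices. For
        PLSR, ``U`` holds the rotations such that ``T = Xc @ U`` exactly
        reproduces the deflation-recurrence scores.
    T, S : ndarray
        Score matrices (n x k), computed on column-centered blocks.
    assoc : ndarray
        Per-component association: canonical correlation (CCA),
        cross-covariance singular value (PLSC), or paired-score sample
        covariance (PLSR).
    x_loadings, y_loadings : ndarray
        Structure coefficients: correlation of each original variable with
        its own block's score columns.
    coef : ndarray or None
        PLSR only: p x m matrix B with ``predict(Xn) = (Xn - x_mean) @ B
        + y_mean``.
    diagnostics : dict
        Tie flags for near-equal singular values, ridge actually applied,
        deflation residual norms, iteration counts.
    """

    method: str
    k: int
    U: np.ndarray
    V: np.ndarray
    T: np.ndarray
    S: np.ndarray
    assoc: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_names: tuple
    y_names: tuple
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef: np.ndarray | None = None
    intercept: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)


def _centered(block: DataBlock):
    mu = block.values.mean(axis=0)
    return block.values - mu, mu


def _cross_cov(Xc: np.ndarray, Yc: np.ndarray) -> np.ndarray:
    return (Xc.T @ Yc) / (Xc.shape[0] - 1)


def _default_k(p: int, m: int) -> int:
    # four components are tested by default, fewer if the blocks are thinner
    return min(p, m, 4)


def _tie_flags(values: np.ndarray) -> list:
    return [
        i for i in range(len(values) - 1) if abs(values[i] - values[i + 1]) < _TIE_TOL
    ]


def _apply_sign_convention(U, V, T, S):
    """Flip (u, v, t, s) jointly so the largest-|.| entry of v is positive."""
    for c in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, c])))
        if V[j, c] < 0:
            U[:, c] *= -1.0
            V[:, c] *= -1.0
            T[:, c] *= -1.0
            S[:, c] *= -1.0
    return U, V, T, S


def _loadings(values: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Correlation of every column of ``values`` with every score column."""
    Vc = values - values.mean(axis=0)
    Tc = scores - scores.mean(axis=0)
    sv = Vc.std(axis=0, ddof=1)
    st = Tc.std(axis=0, ddof=1)
    if np.any(st == 0.0):
        bad = np.flatnonzero(st == 0.0).tolist()
        raise ValidationError(f"zero-variance score column(s): {bad}")
    if np.any(sv == 0.0):
        bad = np.flatnonzero(sv == 0.0).tolist()
        raise ValidationError(f"zero-variance data column(s): {bad}")
    n = values.shape[0]
    corr = (Vc.T @ Tc) / (n - 1) / np.outer(sv, st)
    return np.clip(corr, -1.0, 1.0)


def _inv_sqrt_psd(S: np.ndarray, what: str, ridge) -> tuple[np.ndarray, float]:
    """Inverse symmetric square root of a covariance matrix.

    ``ridge`` may be None (no regularization; singular input raises),
    "auto" (eps = 1e-8 * trace / p) or a float added to the diagonal.
    """
    p = S.shape[0]
    eps = 0.0
    if ridge == "auto":
        eps = 1e-8 * np.trace(S) / p
    elif ridge is not None:
        eps = float(ridge)
    if eps:
        S = S + eps * np.eye(p)
    w, Q = scipy.linalg.eigh(S)
    if w[-1] <= 0 or w[0] <= w[-1] * 1e-12:
        raise NumericalError(
            f"{what} within-block covariance is singular or near-singular; "
            "pass ridge='auto' (or a float) to fit_cca to regularize"
        )
    return (Q * (1.0 / np.sqrt(w))) @ Q.T, eps


def fit_cca(X: DataBlock, Y: DataBlock, k: int | None = None, ridge=None) -> CrossFit:
    """Canonical correlation analysis via SVD of the whitened cross-covariance.

    Successive weight pairs maximize the Pearson correlation of scores
    subject to within-block orthogonality of the canonical variates.
    ``assoc`` holds the canonical correlations, sorted descending, each in
    [0, 1].

    Parameters
    ----------
    ridge : None, "auto" or float
        Diagonal regularization of the within-block covariances. With the
        default None, a singular covariance raises :class:`NumericalError`.
    """
    Xc, xm = _centered(X)
    Yc, ym = _centered(Y)
    p, m = Xc.shape[1], Yc.shape[1]
    k = _default_k(p, m) if k is None else int(k)
    if not 1 <= k <= min(p, m):
        raise ValidationError(f"k={k} out of range 1..min(p={p}, m={m})")
    Sx = _cross_cov(Xc, Xc)
    Sy = _cross_cov(Yc, Yc)
    Cxy = _cross_cov(Xc, Yc)
    Wx, eps_x = _inv_sqrt_psd(Sx, "X", ridge)
    Wy, eps_y = _inv_sqrt_psd(Sy, "Y", ridge)
    P, d, Qt = scipy.linalg.svd(Wx @ Cxy @ Wy, full_matrices=False)
    U = Wx @ P[:, :k]
    V = Wy @ Qt[:k].T
    T = Xc @ U
    S = Yc @ V
    U, V, T, S = _apply_sign_convention(U, V, T, S)
    assoc = np.clip(d[:k], 0.0, 1.0)
    fit = CrossFit(
        method="CCA",
        k=k,
        U=U,
        V=V,
        T=T,
        S=S,
        assoc=assoc,
        x_loadings=_loadings(X.values, T),
        y_loadings=_loadings(Y.values, S),
        x_names=X.variable_names,
        y_names=Y.variable_names,
        x_mean=xm,
        y_mean=ym,
        diagnostics={
            "tied_components": _tie_flags(d),
            "ridge_x": eps_x,
            "ridge_y": eps_y,
        },
    )
    return fit


def fit_plsc(X: DataBlock, Y: DataBlock, k: int | None = None) -> CrossFit:
    """PLS-correlation: one SVD of the cross-covariance matrix, no deflation.

    ``U`` and ``V`` are the top-k unit-norm singular vector pairs of
    ``X'Y/(n-1)``; ``assoc`` the corresponding singular values, descending.
    """
    Xc, xm = _centered(X)
    Yc, ym = _centered(Y)
    p, m = Xc.shape[1], Yc.shape[1]
    k = _default_k(p, m) if k is None else int(k)
    if not 1 <= k <= min(p, m):
        raise ValidationError(f"k={k} out of range 1..min(p={p}, m={m})")
    C = _cross_cov(Xc, Yc)
    P, d, Qt = scipy.linalg.svd(C, full_matrices=False)
    rank = int(np.sum(d > d[0] * 1e-12)) if d.size and d[0] > 0 else 0
    if k > rank:
        raise ValidationError(
            f"k={k} exceeds the rank {rank} of the cross-covariance matrix"
        )
    U = P[:, :k].copy()
    V = Qt[:k].T.copy()
    T = Xc @ U
    S = Yc @ V
    U, V, T, S = _apply_sign_convention(U, V, T, S)
    fit = CrossFit(
        method="PLSC",
        k=k,
        U=U,
        V=V,
        T=T,
        S=S,
        assoc=d[:k].copy(),
        x_loadings=_loadings(X.values, T),
        y_loadings=_loadings(Y.values, S),
        x_names=X.variable_names,
        y_names=Y.variable_names,
        x_mean=xm,
        y_mean=ym,
        diagnostics={"tied_components": _tie_flags(d)},
    )
    return fit


def _plsr_weight(M: np.ndarray, component: int) -> tuple[np.ndarray, float]:
    """Leading left singular vector of the deflated cross-covariance M.

    A dense SVD of the (p x m) matrix is used rather than power iteration:
    it is deterministic, exact, and immune to the slow convergence that
    near-tied singular values cause (common in permuted null fits). The
    sign is fixed by making the largest-|.| entry positive; the spacing to
    the second singular value is returned so ties can be flagged.
    """
    norms = np.linalg.norm(M, axis=0)
    if norms.max() <= 1e-14:
        raise NumericalError(
            f"cross-covariance vanished before component {component}; "
            "X rank exhausted"
        )
    P, d, _ = scipy.linalg.svd(M, full_matrices=False)
    w = P[:, 0]
    j = int(np.argmax(np.abs(w)))
    if w[j] < 0:
        w = -w
    gap = d[0] - d[1] if d.size > 1 else np.inf
    return w, float(gap)


def fit_plsr(X: DataBlock, Y: DataBlock, k: int | None = None) -> CrossFit:
    """PLS2 regression: sequential X-weights with X-only deflation.

    Per component the X-weight is the leading left singular vector of the
    current (deflated) cross-covariance; the X block is then deflated by
    regression on its score. Y is not deflated (it makes no difference to
    the extracted X-scores). The predictive coefficient matrix ``coef``
    satisfies ``predict(Xn) = (Xn - x_mean) @ coef + y_mean``; at
    k = rank(X) with a single response this reproduces OLS.
    """
    Xc, xm = _centered(X)
    Yc, ym = _centered(Y)
    n, p = Xc.shape
    m = Yc.shape[1]
    k = _default_k(p, m) if k is None else int(k)
    rank_x = np.linalg.matrix_rank(Xc)
    if not 1 <= k <= rank_x:
        raise ValidationError(f"k={k} out of range 1..rank(X)={rank_x}")
    Xd = Xc.copy()
    W = np.empty((p, k))
    Pl = np.empty((p, k))  # X-loadings used for deflation
    T = np.empty((n, k))
    gaps = []
    for c in range(k):
        M = Xd.T @ Yc / (n - 1)
        w, gap = _plsr_weight(M, c + 1)
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-14:
            raise NumericalError(f"degenerate score at component {c + 1}")
        pl = Xd.T @ t / tt
        Xd -= np.outer(t, pl)
        W[:, c] = w
        Pl[:, c] = pl
        T[:, c] = t
        gaps.append(gap)
    # rotations: T = Xc @ R exactly (P'W is unit upper triangular)
    R = W @ scipy.linalg.solve_triangular(Pl.T @ W, np.eye(k), lower=False)
    Q = Yc.T @ T / np.sum(T * T, axis=0)  # m x k regression of Y on scores
    V = Q / np.linalg.norm(Q, axis=0)
    S = Yc @ V
    U = R
    U, V, T, S = _apply_sign_convention(U, V, T, S)
    # re-derive W/Q signs consistently with the flipped scores
    coef = R @ (Yc.T @ T / np.sum(T * T, axis=0)).T
    assoc = np.abs(np.sum(T * S, axis=0) / (n - 1))
    fit = CrossFit(
        method="PLSR",
        k=k,
        U=U,
        V=V,
        T=T,
        S=S,
        assoc=assoc,
        x_loadings=_loadings(X.values, T),
        y_loadings=_loadings(Y.values, S),
        x_names=X.variable_names,
        y_names=Y.variable_names,
        x_mean=xm,
        y_mean=ym,
        coef=coef,
        intercept=ym - xm @ coef,
        diagnostics={
            "tied_components": [c for c, g in enumerate(gaps) if g < _TIE_TOL],
            "x_residual_fro": float(np.linalg.norm(Xd)),
        },
    )
    return fit


_FITTERS = {"CCA": fit_cca, "PLSC": fit_plsc, "PLSR": fit_plsr}


def fit_method(method: str, X: DataBlock, Y: DataBlock, k: int | None = None, **kw) -> CrossFit:
    """Dispatch to one of the three fitters by method name."""
    try:
        fitter = _FITTERS[method.upper()]
    except KeyError:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    return fitter(X, Y, k=k, **kw)


def predict_plsr(fit: CrossFit, X_new: np.ndarray) -> np.ndarray:
    """Predict the Y block from new X rows using a fitted PLSR model."""
    if fit.coef is None:
        raise ValidationError(f"method {fit.method} has no predictive coefficients")
    X_new = np.asarray(X_new, dtype=float)
    return (X_new - fit.x_mean) @ fit.coef + fit.y_mean


def structure_coefficients(fit: CrossFit, X: DataBlock, Y: DataBlock):
    """Correlation of every original variable with its own block's scores.

    Entry (j, c) of the first matrix is the Pearson correlation of X's
    variable j with brain-score column c; second matrix analogous for Y.
    All entries lie in [-1, 1].
    """
    if X.variable_names != fit.x_names or Y.variable_names != fit.y_names:
        raise ValidationError("blocks do not match the fitted variable sets")
    return _loadings(X.values, fit.T), _loadings(Y.values, fit.S)
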