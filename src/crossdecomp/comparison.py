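"""Cross-method convergence/divergence report.

Components from different methods are matched greedily on the absolute
cosine similarity of their concatenated (brain + behavior) loading
vectors; loadings rather than raw weights are compared because they are
scale-comparable across methods. The report records, per method, how many
components are significant at a chosen alpha and which behavior dimension
dominates each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import CrossFit
from .errors import ValidationError
from .inference import PermutationReport

__all__ = ["ComponentMatch", "ComparisonReport", "align_components", "compare_methods"]


@dataclass(frozen=True)
class ComponentMatch:
    """One matched component pair (0-based indices into each fit)."""

    index_a: int
    index_b: int
    cosine: float  # non-negative after sign alignment
    sign: int  # +1/-1 flip applied to fit B's component to align it
    brain_cosine: float
    psych_cosine: float


def _loading_vectors(fit: CrossFit) -> np.ndarray:
    return np.vstack([fit.x_loadings, fit.y_loadings])


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    if np.any(na == 0.0) or np.any(nb == 0.0):
        raise ValidationError("zero loading vector; degenerate component")
    return (A.T @ B) / np.outer(na, nb)


def _signed_cos(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def align_components(fitA: CrossFit, fitB: CrossFit) -> list:
    """Greedy one-to-one matching of components across two fits.

    Pairs are taken in decreasing order of |cosine| of concatenated
    loading vectors (ties broken by component indices, so the matching is
    deterministic and symmetric); each component is matched at most once.
    The reported cosine is made non-negative by recording the implied sign
    flip.
    """
    if fitA.x_names != fitB.x_names or fitA.y_names != fitB.y_names:
        raise ValidationError("fits were computed on different variable sets")
    LA, LB = _loading_vectors(fitA), _loading_vectors(fitB)
    cos = _cosine_matrix(LA, LB)
    order = sorted(
        ((i, j) for i in range(fitA.k) for j in range(fitB.k)),
        key=lambda ij: (-abs(cos[ij]), ij[0], ij[1]),
    )
    used_a, used_b, matches = set(), set(), []
    p = fitA.x_loadings.shape[0]
    for i, j in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        sign = 1 if cos[i, j] >= 0 else -1
        matches.append(
            ComponentMatch(
                index_a=i,
                index_b=j,
                cosine=abs(float(cos[i, j])),
                sign=sign,
                brain_cosine=sign * _signed_cos(LA[:p, i], LB[:p, j]),
                psych_cosine=sign * _signed_cos(LA[p:, i], LB[p:, j]),
            )
        )
    matches.sort(key=lambda mt: mt.index_a)
    return matches


def dominant_dimension(fit: CrossFit, component: int) -> str:
    """Behavior variable with the largest-|loading| on one component."""
    j = int(np.argmax(np.abs(fit.y_loadings[:, component])))
    return fit.y_names[j]


@dataclass
class ComparisonReport:
    """Cross-method summary: significance counts, alignments, dominant dims."""

    methods: tuple
    alpha: float
    n_significant: dict
    p_values: dict
    dominant: dict  # method -> list of behavior-dimension names per component
    alignments: dict  # (methodA, methodB) -> list of ComponentMatch

    def leading_match(self, method_a: str, method_b: str) -> ComponentMatch:
        """The match involving both methods' component 1."""
        for mt in self.alignments[(method_a, method_b)]:
            if mt.index_a == 0:
                return mt
        raise KeyError("no match for component 1")

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "alpha": self.alpha,
            "n_significant": dict(self.n_significant),
            "p_values": {mth: v.tolist() for mth, v in self.p_values.items()},
            "dominant_dimension": {m: list(v) for m, v in self.dominant.items()},
            "alignments": {
                f"{a}|{b}": [
                    {
                        "component_a": mt.index_a + 1,
                        "component_b": mt.index_b + 1,
                        "cosine": mt.cosine,
                        "sign": mt.sign,
                        "brain_cosine": mt.brain_cosine,
                        "psych_cosine": mt.psych_cosine,
                    }
                    for mt in matches
                ]
                for (a, b), matches in self.alignments.items()
            },
        }


def compare_methods(fits, reports, alpha: float = 0.05) -> ComparisonReport:
    """Build the divergence report across methods fit on identical blocks.

    ``fits`` and ``reports`` are parallel lists (one permutation report per
    fit, same method). Components with p < alpha count as significant; each
    significant component is labeled with its dominant behavior dimension
    (labels are computed for all components, significant or not).
    """
    if len(fits) != len(reports):
        raise ValidationError("need exactly one permutation report per fit")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must lie in [0, 1], got {alpha}")
    for fit, rep in zip(fits, reports):
        if fit.method != rep.method:
            raise ValidationError(
                f"fit/report method mismatch: {fit.method} vs {rep.method}"
            )
    methods = tuple(f.method for f in fits)
    if len(set(methods)) != len(methods):
        raise ValidationError(f"duplicate methods in comparison: {methods}")
    n_sig = {
        f.method: int(np.sum(r.p_values < alpha)) for f, r in zip(fits, reports)
    }
    p_values = {r.method: r.p_values.copy() for r in reports}
    dominant = {
        f.method: [dominant_dimension(f, c) for c in range(f.k)] for f in fits
    }
    alignments = {}
    for i, fa in enumerate(fits):
        for fb in fits[i + 1 :]:
            alignments[(fa.method, fb.method)] = align_components(fa, fb)
    return ComparisonReport(
        methods=methods,
        alpha=alpha,
        n_significant=n_sig,
        p_values=p_values,
        dominant=dominant,
        alignments=alignments,
    )
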