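"""Inference layer: back-transformed marginal means, pairwise contrasts,
compact letter displays and McFadden's pseudo-R-squared.

Marginal means are computed on the linear-predictor (log) scale and
back-transformed: ``mean = exp(eta)``, ``CI = exp(eta +/- 1.96 se)``, so the
interval is symmetric on the log scale.  Pairwise level comparisons are Wald
z tests with optional Bonferroni adjustment (the exactly implementable
multiplicity correction; toolchains defaulting to Tukey may disagree on
borderline letters only).

The compact letter display assigns each level one or more letters such that
two levels share a letter if and only if their adjusted p-value exceeds
alpha.  Letters correspond to cliques of the non-significance graph; the
implementation finds a minimum edge clique cover (exact for the small level
counts that arise from breakpoint schemes), so the letter count is minimal
subject to the sharing constraint.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DesignError
from .gammaglm import DesignSpec, GlmFit

__all__ = ["MarginalMean", "PairwiseTable", "marginal_mean", "pairwise", "cld", "mcfadden"]

Z95 = 1.96  # normal 95% multiplier


@dataclass(frozen=True)
class MarginalMean:
    """Model-predicted mass (kg) with a back-transformed 95% CI."""

    at: object
    mean: float
    lower: float
    upper: float

    @property
    def span(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class PairwiseTable:
    """All pairwise level contrasts plus per-level CLD letters."""

    table: pd.DataFrame  # columns: level_a, level_b, estimate, se, z, p, p_adj
    letters: dict[str, str]
    alpha: float


def _level_row(design: DesignSpec, label: str) -> np.ndarray:
    levels = list(design.categories)
    if label not in levels:
        raise DesignError(f"unknown category label '{label}'; levels: {levels}")
    L = len(levels)
    x = np.zeros(L)
    x[0] = 1.0
    if design.coding == "treatment":
        j = levels.index(label)
        if j > 0:
            x[j] = 1.0
    else:  # sum coding
        j = levels.index(label)
        if j < L - 1:
            x[j + 1] = 1.0
        else:
            x[1:] = -1.0
    return x


def _predictor_row(fit: GlmFit, at) -> np.ndarray:
    design = fit.design
    if design.predictor_mode == "categorical":
        return _level_row(design, at)
    if design.predictor_mode == "continuous":
        if len(fit.coefficients) == 1:  # intercept-only
            return np.ones(1)
        return np.array([1.0, float(at)])
    # smooth: evaluate the basis at the point
    from .smooth import basis_row  # local import to avoid a cycle

    return basis_row(fit.design.basis, float(at))


def marginal_mean(fit: GlmFit, at) -> MarginalMean:
    """Predicted mean at a category label or predictor value, with 95% CI.

    Delta method on the linear predictor: ``se^2 = x' V x``; the interval is
    ``exp(eta +/- 1.96 se)``, i.e. symmetric on the log scale.
    """
    x = _predictor_row(fit, at)
    eta = float(x @ fit.coefficients)
    se = float(np.sqrt(x @ fit.covariance @ x))
    return MarginalMean(
        at=at,
        mean=float(np.exp(eta)),
        lower=float(np.exp(eta - Z95 * se)),
        upper=float(np.exp(eta + Z95 * se)),
    )


def pairwise(fit: GlmFit, adjust: str = "bonferroni", alpha: float = 0.05) -> PairwiseTable:
    """Wald z tests on all pairwise level contrasts of a categorical fit.

    ``adjust`` is "bonferroni" (p multiplied by the number of pairs, capped
    at 1) or "none".
    """
    if fit.design.predictor_mode != "categorical":
        raise DesignError("pairwise comparisons require a categorical design")
    if adjust not in ("none", "bonferroni"):
        raise DesignError(f"unknown adjustment '{adjust}'")
    levels = list(fit.design.categories)
    if len(levels) < 2:
        raise DesignError("need at least 2 levels for pairwise comparisons")
    pairs = list(itertools.combinations(range(len(levels)), 2))
    m = len(pairs)
    rows = []
    pmat = np.ones((len(levels), len(levels)))
    for i, j in pairs:
        c = _level_row(fit.design, levels[i]) - _level_row(fit.design, levels[j])
        est = float(c @ fit.coefficients)
        se = float(np.sqrt(c @ fit.covariance @ c))
        z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        pmat[i, j] = pmat[j, i] = p_adj
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "estimate": est,
                "se": se,
                "z": z,
                "p": p,
                "p_adj": p_adj,
            }
        )
    letters = cld(levels, pmat, alpha=alpha)
    return PairwiseTable(table=pd.DataFrame(rows), letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# compact letter display


def _letter(i: int) -> str:
    letters = string.ascii_lowercase
    if i < len(letters):
        return letters[i]
    return letters[i // len(letters) - 1] + letters[i % len(letters)]


def _maximal_cliques(adj: np.ndarray) -> list[frozenset[int]]:
    """Maximal cliques of a small undirected graph (Bron-Kerbosch, no pivot)."""
    n = adj.shape[0]
    neigh = [frozenset(np.flatnonzero(adj[i]).tolist()) - {i} for i in range(n)]
    out: list[frozenset[int]] = []

    def bk(r: frozenset, p: frozenset, x: frozenset) -> None:
        if not p and not x:
            out.append(r)
            return
        for v in sorted(p):
            bk(r | {v}, p & neigh[v], x & neigh[v])
            p = p - {v}
            x = x | {v}

    bk(frozenset(), frozenset(range(n)), frozenset())
    return out


def cld(levels, pairwise_p: np.ndarray, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from a symmetric matrix of adjusted p-values.

    Two levels share at least one letter iff ``p > alpha``; the number of
    distinct letters is minimal subject to that constraint (minimum clique
    cover of the non-significance graph).  Letters are assigned in level
    order starting at "a".
    """
    levels = list(levels)
    P = np.asarray(pairwise_p, dtype=float)
    if P.shape != (len(levels), len(levels)):
        raise DataError("p matrix shape does not match the level count")
    if not np.allclose(P, P.T, equal_nan=True):
        raise DataError("pairwise p matrix must be symmetric")
    n = len(levels)
    ns = P > alpha  # non-significant adjacency
    np.fill_diagonal(ns, False)

    cliques = _maximal_cliques(ns)
    edges = {frozenset((i, j)) for i in range(n) for j in range(i + 1, n) if ns[i, j]}
    # smallest subset of maximal cliques covering every NS edge and vertex
    cliques = sorted(cliques, key=lambda c: sorted(c))
    chosen: list[frozenset[int]] | None = None
    for r in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, r):
            covered_v = frozenset().union(*combo)
            if len(covered_v) < n:
                continue
            covered_e = {
                frozenset((i, j)) for c in combo for i in c for j in c if i < j
            }
            if edges <= covered_e:
                chosen = list(combo)
                break
        if chosen is not None:
            break
    assert chosen is not None  # singletons alone always cover
    chosen.sort(key=lambda c: sorted(c))
    out = {lev: "" for lev in levels}
    for k, clique in enumerate(chosen):
        for i in sorted(clique):
            out[levels[i]] += _letter(k)
    return out


def mcfadden(fit: GlmFit, null_fit: GlmFit) -> float:
    """McFadden's pseudo-R2: ``1 - loglik(fit)/loglik(null)``.

    The null must be the intercept-only fit on the same data; each fit uses
    its own profiled shape.
    """
    if fit.n != null_fit.n or not np.isclose(fit.response_sum, null_fit.response_sum):
        raise DataError("fit and null_fit were not computed on the same data")
    if len(null_fit.coefficients) != 1:
        raise DataError("null_fit must be intercept-only")
    return float(1.0 - fit.loglik / null_fit.loglik)
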