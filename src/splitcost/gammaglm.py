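"""Gamma GLM with log link: IRLS fitting, profile-ML shape, likelihood AIC.

The mean model is ``E[y] = exp(X beta)`` with ``Var[y] = mu^2 / k`` for Gamma
shape ``k``.  For the log link the GLM working weights are identically 1, so
each IRLS step is an ordinary least-squares solve of the working response
``z = eta + (y - mu)/mu`` on the design.  Iteration stops when the relative
change in deviance falls below 1e-10 (cap 100 iterations).

After the mean fit, the shape is estimated by maximizing the profile Gamma
log-likelihood given the fitted means (one-dimensional bracketed search).
The reported AIC is ``-2*loglik + 2*(p + 1)`` — the full Gamma likelihood
with the shape counted as a parameter.  Software packages differ in their
Gamma-AIC dispersion conventions, so differences in AIC between models fit to
the same data are the meaningful output, not absolute values.

The coefficient covariance is the inverse expected information scaled by the
dispersion: ``(X'X)^{-1} / shape_hat`` (unit working weights).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import DataError, DesignError, FitError
from .simgen import MASS_COL, TIMING_COL

__all__ = [
    "DesignSpec",
    "GlmFit",
    "fit",
    "gamma_loglik",
    "estimate_shape",
    "aic",
]

#: upper cap for the shape search; reached only for (near-)degenerate fits
MAX_SHAPE = 1e8

#: relative-deviance convergence tolerance and iteration cap for IRLS
IRLS_TOL = 1e-10
IRLS_MAXITER = 100

CATEGORY_COL = "category"


@dataclass(frozen=True)
class DesignSpec:
    """What the linear predictor contains.

    predictor_mode : "continuous" (intercept + timing), "categorical"
        (one mean per category of the ``category`` column), or "smooth"
        (penalized spline basis, built by :mod:`splitcost.smooth`).
    categories : level labels in display order (categorical mode); the first
        level is the reference under treatment coding.
    coding : "treatment" (default) or "sum"; marginal means are invariant to
        this choice.
    basis : smooth-basis handle (smooth mode only).
    """

    predictor_mode: str
    categories: tuple[str, ...] | None = None
    coding: str = "treatment"
    basis: Any = None

    def __post_init__(self) -> None:
        if self.predictor_mode not in ("continuous", "categorical", "smooth"):
            raise DesignError(f"unknown predictor_mode '{self.predictor_mode}'")
        if self.predictor_mode == "categorical":
            if not self.categories or len(self.categories) < 1:
                raise DesignError("categorical design requires category labels")
            if self.coding not in ("treatment", "sum"):
                raise DesignError(f"unknown coding '{self.coding}'")

    @classmethod
    def continuous(cls) -> "DesignSpec":
        return cls("continuous")

    @classmethod
    def categorical(cls, categories: Sequence[str], coding: str = "treatment") -> "DesignSpec":
        return cls("categorical", categories=tuple(categories), coding=coding)


@dataclass(frozen=True)
class GlmFit:
    """A fitted Gamma GLM (log link)."""

    coefficients: np.ndarray
    covariance: np.ndarray
    shape_hat: float
    loglik: float
    aic: float
    n: int
    design: DesignSpec
    converged: bool
    column_names: tuple[str, ...] = ()
    edf: float | None = None  # effective df (smooth fits only)
    response_sum: float = 0.0  # identity check for pseudo-R2 pairing

    def to_json_dict(self) -> dict:
        return {
            "coefficients": dict(zip(self.column_names, map(float, self.coefficients))),
            "shape": float(self.shape_hat),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n": self.n,
            "converged": self.converged,
            "predictor_mode": self.design.predictor_mode,
        }


# ---------------------------------------------------------------------------
# likelihood pieces


def gamma_loglik(y, mu, shape: float) -> float:
    """Gamma log-likelihood, mean parameterization.

    ``sum_i [ k ln(k/mu_i) - lnGamma(k) + (k-1) ln y_i - k y_i/mu_i ]``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise DataError(f"length mismatch: y has {y.shape}, mu has {mu.shape}")
    if shape <= 0:
        raise DataError(f"shape must be > 0, got {shape}")
    if np.any(y <= 0) or np.any(mu <= 0):
        raise DataError("y and mu must be strictly positive")
    k = float(shape)
    return float(
        np.sum(k * np.log(k / mu) - special.gammaln(k) + (k - 1) * np.log(y) - k * y / mu)
    )


def estimate_shape(y, mu, max_shape: float = MAX_SHAPE) -> float:
    """Profile-ML Gamma shape given fitted means.

    Solves the score equation ``ln k + 1 - digamma(k) = mean(y/mu - ln(y/mu))``
    by bracketed root finding (tolerance 1e-8).  If the data are (near-)exactly
    fitted the optimum diverges; the search is then capped at ``max_shape``
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise DataError("length mismatch between y and mu")
    if np.any(y <= 0) or np.any(mu <= 0):
        raise DataError("y and mu must be strictly positive")
    r = y / mu
    c = float(np.mean(r - np.log(r)))  # >= 1, == 1 iff y == mu everywhere

    def score(k: float) -> float:
        # d loglik/dk / n = ln k + 1 - digamma(k) - c; limit 1 - c as k -> inf
        return np.log(k) + 1.0 - special.digamma(k) - c

    # score decreases from +inf (k -> 0) toward 1 - c <= 0
    if score(max_shape) > 0:
        warnings.warn(
            "shape MLE diverges (response is exactly fitted); "
            f"capping at {max_shape:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(max_shape)
    lo = 1e-8
    if score(lo) < 0:
        raise FitError("shape score not bracketable from below")
    return float(optimize.brentq(score, lo, max_shape, xtol=1e-8, rtol=1e-12))


# ---------------------------------------------------------------------------
# design matrices


def _categorical_matrix(
    labels: np.ndarray, design: DesignSpec
) -> tuple[np.ndarray, list[str]]:
    levels = list(design.categories)
    unknown = set(labels) - set(levels)
    if unknown:
        raise DesignError(f"data contain labels not in design: {sorted(unknown)}")
    n, L = len(labels), len(levels)
    X = np.ones((n, L))
    names = ["intercept"]
    if design.coding == "treatment":
        for j, lev in enumerate(levels[1:], start=1):
            X[:, j] = (labels == lev).astype(float)
            names.append(f"[{lev}]")
    else:  # sum coding
        last = levels[-1]
        for j, lev in enumerate(levels[:-1], start=1):
            X[:, j] = (labels == lev).astype(float) - (labels == last).astype(float)
            names.append(f"[{lev}]")
    return X, names


def design_matrix(design: DesignSpec, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Build the model matrix for a dataset (continuous or categorical mode)."""
    if design.predictor_mode == "continuous":
        t = data[TIMING_COL].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(t)), t]), ["intercept", TIMING_COL]
    if design.predictor_mode == "categorical":
        if CATEGORY_COL not in data.columns:
            raise DesignError("categorical design requires a 'category' column")
        labels = data[CATEGORY_COL].to_numpy(dtype=object)
        return _categorical_matrix(labels, design)
    raise DesignError("smooth designs are fit via splitcost.smooth.fit_smooth")


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    for j in range(1, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :j]) < j:
            raise DesignError(f"design is rank deficient: column '{names[j - 1]}' is aliased")
    raise DesignError("design is rank deficient")


# ---------------------------------------------------------------------------
# fitting


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool, list[float]]:
    """Log-link Gamma IRLS; returns (beta, converged, deviance trace)."""
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    dev = np.inf
    trace: list[float] = []
    converged = False
    for _ in range(IRLS_MAXITER):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        new_dev = _gamma_deviance(y, np.exp(X @ beta))
        trace.append(new_dev)
        if np.isfinite(dev) and abs(dev - new_dev) <= IRLS_TOL * (abs(dev) + 0.1):
            converged = True
            dev = new_dev
            break
        dev = new_dev
    return beta, converged, trace


def fit(design: DesignSpec, data: pd.DataFrame) -> GlmFit:
    """Fit a Gamma log-link GLM by IRLS and profile the shape.

    ``data`` must contain ``mass_kg`` (positive) and either ``timing_day``
    (continuous mode) or ``category`` (categorical mode).
    """
    y = data[MASS_COL].to_numpy(dtype=float)
    if len(y) == 0:
        raise DataError("empty dataset")
    if np.any(y <= 0):
        raise DataError("response mass_kg must be strictly positive")
    X, names = design_matrix(design, data)
    if len(y) <= X.shape[1]:
        raise DesignError(f"n={len(y)} rows cannot identify p={X.shape[1]} coefficients")
    _check_rank(X, names)

    beta, converged, trace = irls(X, y)
    if not converged:
        raise FitError(
            f"IRLS did not converge in {IRLS_MAXITER} iterations; "
            f"deviance trace tail: {trace[-5:]}"
        )
    mu = np.exp(X @ beta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        shape_hat = estimate_shape(y, mu)
    ll = gamma_loglik(y, mu, shape_hat)
    p = X.shape[1]
    cov = np.linalg.inv(X.T @ X) / shape_hat
    cov = (cov + cov.T) / 2.0  # enforce symmetry against round-off
    return GlmFit(
        coefficients=beta,
        covariance=cov,
        shape_hat=shape_hat,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * (p + 1),
        n=len(y),
        design=design,
        converged=converged,
        column_names=tuple(names),
        response_sum=float(np.sum(y)),
    )


def fit_null(data: pd.DataFrame) -> GlmFit:
    """Intercept-only fit (the null model for pseudo-R2)."""
    y = data[MASS_COL].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise DataError("response mass_kg must be strictly positive")
    if len(y) < 2:
        raise DataError("need at least 2 rows for the null fit")
    mu = np.full_like(y, y.mean())  # closed form: sum((y-mu)/mu) = 0 at mu = ybar
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        shape_hat = estimate_shape(y, mu)
    ll = gamma_loglik(y, mu, shape_hat)
    X = np.ones((len(y), 1))
    return GlmFit(
        coefficients=np.array([np.log(y.mean())]),
        covariance=np.array([[1.0 / (len(y) * shape_hat)]]),
        shape_hat=shape_hat,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * 2,
        n=len(y),
        design=DesignSpec("continuous"),
        converged=True,
        column_names=("intercept",),
        response_sum=float(np.sum(y)),
    )


def aic(fit_result: GlmFit) -> float:
    """``-2*loglik + 2*(p+1)`` (shape counted); compare differences, not levels."""
    if not fit_result.converged:
        raise FitError("AIC requested for a non-converged fit")
    return float(fit_result.aic)
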